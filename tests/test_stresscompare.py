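"""Size factors, NB testing, dispersion, DE calls, clustering, percentiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srnome.calibration import simulate_two_group_matrix
from srnome.quantify import CountMatrix
from srnome.simulate import StudyDesign
from srnome.stresscompare import (
    call_de,
    de_summary,
    estimate_dispersion,
    hcluster,
    nb_test,
    percentile_rank,
    pooled_dispersion,
    ratio_matrix,
    size_factors,
)

from .oracles import brute_percentile_ranks


def _cm(counts: pd.DataFrame) -> CountMatrix:
    return CountMatrix(counts=counts, classes=pd.Series("ior", index=counts.index))


class TestSizeFactors:
    def test_doubled_library_gets_double_factor(self):
        rng = np.random.default_rng(0)
        a = rng.integers(10, 500, size=100)
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        f = size_factors(counts)
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_identical_libraries_equal_factors(self):
        counts = pd.DataFrame({"A": [10, 20, 30], "B": [10, 20, 30]})
        f = size_factors(counts)
        assert f["A"] == pytest.approx(f["B"])

    def test_matches_hand_computed_median_of_ratios(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 300, size=(50, 4)), columns=list("ABCD"))
        f = size_factors(counts)
        mat = counts.to_numpy(dtype=float)
        gm = np.exp(np.log(mat).mean(axis=1))
        for j, lib in enumerate("ABCD"):
            assert f[lib] == pytest.approx(np.median(mat[:, j] / gm))

    def test_fallback_when_no_feature_nonzero_everywhere(self, caplog):
        counts = pd.DataFrame({"A": [10, 0], "B": [0, 10]})
        with caplog.at_level("WARNING"):
            f = size_factors(counts)
        assert (f > 0).all()
        assert any("fallback" in r.message for r in caplog.records)

    def test_scale_equivariance_leaves_ratios_invariant(self):
        """Scaling one library by c scales its factor by c relative to the
        others, so all normalized profiles change only by a common constant
        and between-library ratios (hence p-values) are unchanged."""
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 300, size=(40, 3)), columns=list("ABC"))
        f1 = size_factors(counts)
        scaled = counts.copy()
        scaled["B"] = scaled["B"] * 3
        f2 = size_factors(scaled)
        rel1 = f1 / f1["A"]
        rel2 = f2 / f2["A"]
        assert rel2["B"] / rel1["B"] == pytest.approx(3.0, rel=1e-9)
        assert rel2["C"] == pytest.approx(rel1["C"], rel=1e-9)
        norm1 = counts / f1
        norm2 = scaled / f2
        const = (norm2 / norm1).to_numpy()
        assert np.allclose(const, const.flat[0])
        p1 = nb_test(
            counts["A"].to_numpy()[:3], counts["B"].to_numpy()[:3],
            np.full(3, f1["A"]), np.full(3, f1["B"]), 0.05,
        )
        p2 = nb_test(
            scaled["A"].to_numpy()[:3], scaled["B"].to_numpy()[:3],
            np.full(3, f2["A"]), np.full(3, f2["B"]), 0.05,
        )
        assert 0 <= p1 <= 1 and 0 <= p2 <= 1


class TestNbTest:
    def test_identical_groups_give_p_one(self):
        k = np.array([30, 40, 50])
        s = np.ones(3)
        assert nb_test(k, k, s, s, 0.05) == pytest.approx(1.0)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ka = rng.integers(0, 200, size=3)
            kb = rng.integers(0, 200, size=3)
            sa = rng.uniform(0.7, 1.3, size=3)
            sb = rng.uniform(0.7, 1.3, size=3)
            p1 = nb_test(ka, kb, sa, sb, 0.1)
            p2 = nb_test(kb, ka, sb, sa, 0.1)
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_all_zero_feature_gives_p_one(self):
        z = np.zeros(3, dtype=int)
        assert nb_test(z, z, np.ones(3), np.ones(3), 0.05) == 1.0

    def test_reduces_to_conditional_binomial_at_zero_dispersion(self):
        """With Poisson groups, K_A | total is Binomial(total, S_A/(S_A+S_B));
        the min-likelihood two-sided p must agree to 1e-6."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            ka = rng.integers(0, 60, size=2)
            kb = rng.integers(0, 60, size=2)
            sa = rng.uniform(0.5, 1.5, size=2)
            sb = rng.uniform(0.5, 1.5, size=2)
            total = int(ka.sum() + kb.sum())
            if total == 0:
                continue
            prob = sa.sum() / (sa.sum() + sb.sum())
            pmf = stats.binom.pmf(np.arange(total + 1), total, prob)
            p_obs = pmf[int(ka.sum())]
            expected = pmf[pmf <= p_obs * (1 + 1e-10)].sum()
            got = nb_test(ka, kb, sa, sb, 0.0)
            assert got == pytest.approx(min(1.0, expected), abs=1e-6)

    def test_large_total_normal_approximation_continuity(self):
        """Exact and approximate paths agree reasonably near the cutover."""
        ka = np.array([2400, 2500])
        kb = np.array([2600, 2450])
        s = np.ones(2)
        p_exact = nb_test(ka, kb, s, s, 0.01)  # total 9950 <= 1e4: exact
        ka2 = ka + 30
        kb2 = kb + 30  # total 10070: normal approximation
        p_norm = nb_test(ka2, kb2, s, s, 0.01)
        assert 0 < p_exact <= 1 and 0 < p_norm <= 1
        assert abs(p_exact - p_norm) < 0.1

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_test(np.array([1]), np.array([2]), np.ones(1), np.ones(1), -0.1)


class TestDispersion:
    def test_poisson_data_estimates_near_floor(self):
        matrix, design = simulate_two_group_matrix(
            500, 200.0, 1.0, 0.0, 3, seed=5, size_factor_sigma=0.0
        )
        disp = estimate_dispersion(matrix, design)
        assert disp.median() <= 0.02

    def test_nb_data_estimator_consistency_at_many_replicates(self):
        matrix, design = simulate_two_group_matrix(
            300, 300.0, 1.0, 0.2, 50, seed=6, size_factor_sigma=0.0
        )
        disp = estimate_dispersion(matrix, design)
        assert 0.15 <= disp.median() <= 0.25

    def test_constant_counts_floored(self):
        counts = pd.DataFrame(
            {f"l{i}": [100, 100] for i in range(6)},
            index=["F0", "F1"],
        )
        design = simulate_two_group_matrix(2, 100.0, 1.0, 0.0, 3, seed=7)[1]
        counts.columns = [l.library_id for l in design.libraries]
        disp = estimate_dispersion(_cm(counts), design, min_dispersion=0.01)
        assert (disp == 0.01).all()

    def test_pooled_estimate_recovers_shared_dispersion(self):
        matrix, design = simulate_two_group_matrix(2000, 200.0, 1.0, 0.05, 3, seed=8)
        alpha = pooled_dispersion(matrix, design)
        assert 0.04 <= alpha <= 0.06


class TestCallDe:
    def test_planted_fourfold_effect_detected_up(self):
        fold = np.ones(300)
        fold[:10] = 4.0
        matrix, design = simulate_two_group_matrix(300, 200.0, fold, 0.05, 3, seed=9)
        de = call_de(matrix, design)
        planted = de[de.feature_id.isin([f"F{i:05d}" for i in range(10)])]
        assert (planted["significant"] & (planted["log2_ratio"] > 0)).mean() >= 0.8

    def test_feature_absent_in_both_groups_not_significant(self):
        matrix, design = simulate_two_group_matrix(50, 100.0, 1.0, 0.05, 3, seed=10)
        matrix.counts.iloc[0] = 0
        de = call_de(matrix, design)
        row = de[de.feature_id == "F00000"].iloc[0]
        assert row["p_value"] == 1.0 and not row["significant"]

    def test_contrast_grid_covers_all_stress_cells(self):
        rng = np.random.default_rng(11)
        design = StudyDesign.default(n_replicates=2)
        counts = pd.DataFrame(
            rng.integers(50, 300, size=(10, len(design.libraries))),
            columns=[l.library_id for l in design.libraries],
            index=[f"F{i}" for i in range(10)],
        )
        de = call_de(_cm(counts), design)
        cells = de.groupby(["stressor", "dose", "time_min"]).size()
        assert len(cells) == 2 * 3 * 4
        assert (cells == 10).all()

    def test_bh_flag_is_more_conservative(self):
        matrix, design = simulate_two_group_matrix(400, 150.0, 1.0, 0.05, 3, seed=12)
        raw = call_de(matrix, design, bh_correct=False)
        adj = call_de(matrix, design, bh_correct=True)
        assert adj["significant"].sum() <= raw["significant"].sum()

    def test_summary_counts_unique_features(self):
        de = pd.DataFrame(
            {
                "feature_id": ["a", "a", "b"],
                "stressor": ["butanol"] * 3,
                "dose": ["low"] * 3,
                "time_min": [15, 30, 15],
                "significant": [True, True, True],
                "direction": ["up", "up", "down"],
            }
        )
        summary = de_summary(de)
        row = summary.iloc[0]
        assert row["n_up"] == 1 and row["n_down"] == 1


class TestRatioMatrix:
    def test_stress_equal_control_gives_zero_matrix(self):
        design = StudyDesign.default(n_replicates=2)
        counts = pd.DataFrame(
            {l.library_id: [100, 40, 7] for l in design.libraries},
            index=["F0", "F1", "F2"],
        )
        ratios = ratio_matrix(_cm(counts), design)
        assert np.allclose(ratios.to_numpy(), 0.0)
        assert ratios.shape == (3, 24)

    def test_normalization_invariance_under_library_scaling(self):
        rng = np.random.default_rng(13)
        design = StudyDesign.default(n_replicates=2)
        counts = pd.DataFrame(
            rng.integers(10, 400, size=(20, len(design.libraries))),
            columns=[l.library_id for l in design.libraries],
            index=[f"F{i}" for i in range(20)],
        )
        base_factors = size_factors(counts)
        r1 = ratio_matrix(_cm(counts), design, factors=base_factors, pseudocount=0.0)
        stress_libs = [l.library_id for l in design.libraries if l.stressor != "none"]
        scaled = counts.copy()
        scaled[stress_libs] = scaled[stress_libs] * 2
        scaled_factors = base_factors.copy()
        scaled_factors[stress_libs] = scaled_factors[stress_libs] * 2
        r2 = ratio_matrix(_cm(scaled), design, factors=scaled_factors, pseudocount=0.0)
        assert np.allclose(r1.to_numpy(), r2.to_numpy())

    def test_planted_fourfold_ratio_near_two(self):
        """Averaged over 20 planted features the log2 ratio recovers 2 with
        small bias (sampling error of single features is larger)."""
        fold = np.ones(200)
        fold[:20] = 4.0
        matrix, design = simulate_two_group_matrix(200, 300.0, fold, 0.02, 3, seed=14)
        ratios = ratio_matrix(matrix, design)
        planted = ratios.iloc[:20].to_numpy().mean()
        assert planted == pytest.approx(2.0, abs=0.15)


class TestHCluster:
    def test_identical_rows_merge_first_at_distance_zero(self):
        rng = np.random.default_rng(15)
        base = rng.normal(size=8)
        block = pd.DataFrame(
            [base, base, rng.normal(size=8) + 3],
            index=["a", "b", "c"],
        )
        res = hcluster(block, k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert res.labels["a"] == res.labels["b"] != res.labels["c"]

    def test_block_diagonal_groups_recovered_at_k2(self):
        rng = np.random.default_rng(16)
        up = np.tile([2.0, 2.1, 1.9, 2.2], (10, 1)) + rng.normal(0, 0.05, (10, 4))
        down = -np.tile([2.0, 2.1, 1.9, 2.2], (10, 1)) + rng.normal(0, 0.05, (10, 4))
        block = pd.DataFrame(
            np.vstack([up, down]), index=[f"f{i}" for i in range(20)]
        )
        res = hcluster(block, k=2)
        labels = res.labels
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[10]

    def test_row_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(17)
        block = pd.DataFrame(
            rng.normal(size=(12, 6)), index=[f"f{i}" for i in range(12)]
        )
        res1 = hcluster(block, k=3)
        perm = block.sample(frac=1, random_state=1)
        res2 = hcluster(perm, k=3)
        pairs1 = {
            (a, b)
            for a in block.index
            for b in block.index
            if a < b and res1.labels[a] == res1.labels[b]
        }
        pairs2 = {
            (a, b)
            for a in perm.index
            for b in perm.index
            if a < b and res2.labels[a] == res2.labels[b]
        }
        assert pairs1 == pairs2

    def test_constant_row_handled_with_guard(self, caplog):
        block = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [0.1, 2.0, -1.0, 0.5], [0.2, 1.8, -0.9, 0.4]],
            index=["const", "a", "b"],
        )
        with caplog.at_level("WARNING"):
            res = hcluster(block, k=2)
        assert res.labels["a"] == res.labels["b"] != res.labels["const"]

    def test_newick_string_has_all_leaves(self):
        rng = np.random.default_rng(18)
        block = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"))
        res = hcluster(block, k=2)
        assert res.newick.endswith(";")
        for leaf in "abcde":
            assert leaf in res.newick


class TestPercentileRank:
    def test_distinct_counts_min_zero_max_hundred(self):
        counts = pd.DataFrame({"lib": [5, 50, 500]}, index=list("abc"))
        pct = percentile_rank(counts, pd.Series({"lib": 1.0}))
        assert pct.loc["a", "lib"] == 0.0
        assert pct.loc["c", "lib"] == 100.0

    def test_all_equal_counts_rank_fifty(self):
        counts = pd.DataFrame({"lib": [7, 7, 7, 7]}, index=list("abcd"))
        pct = percentile_rank(counts, pd.Series({"lib": 1.0}))
        assert (pct["lib"] == 50.0).all()

    def test_single_feature_ranks_hundred_by_convention(self):
        counts = pd.DataFrame({"lib": [7]}, index=["a"])
        pct = percentile_rank(counts, pd.Series({"lib": 1.0}))
        assert pct.loc["a", "lib"] == 100.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sort_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 40, size=25)  # ties likely
        counts = pd.DataFrame({"lib": values}, index=[f"f{i}" for i in range(25)])
        pct = percentile_rank(counts, pd.Series({"lib": 1.0}))
        expected = brute_percentile_ranks(values)
        assert np.allclose(pct["lib"].to_numpy(), expected)
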