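"""Properties of the synthetic genome + count generator."""

import numpy as np
import pytest

from srnome.annotation import derive_iors, flank_windows
from srnome.simulate import (
    PackingError,
    StudyDesign,
    TruthRecord,
    simulate_counts,
    simulate_genome,
)


class TestDesign:
    def test_default_design_shape(self):
        design = StudyDesign.default(n_replicates=2)
        df = design.to_frame()
        assert df["condition_id"].nunique() == 7
        assert sorted(df["time_min"].unique()) == [15, 30, 60, 75]
        assert len(df) == 7 * 4 * 2
        assert design.read_length == 50

    def test_dose_mm_grading(self):
        df = StudyDesign.default().to_frame()
        butanol = df[df.stressor == "butanol"].groupby("dose")["dose_mM"].first()
        assert butanol["low"] == 30 and butanol["medium"] == 60 and butanol["high"] == 90
        butyrate = df[df.stressor == "butyrate"].groupby("dose")["dose_mM"].first()
        assert butyrate["low"] == 30 and butyrate["medium"] == 40 and butyrate["high"] == 50

    def test_two_control_conditions_rejected(self):
        design = StudyDesign.default()
        bad = StudyDesign(
            libraries=[
                lib.__class__(**{**lib.__dict__, "condition_id": f"c{i}"})
                if lib.stressor == "none"
                else lib
                for i, lib in enumerate(design.libraries)
            ]
        )
        with pytest.raises(ValueError, match="no-stress"):
            bad.validate()


class TestGenome:
    def test_gc_content_near_target(self, synthetic_dataset):
        annotation, _, _, _ = synthetic_dataset
        seq = annotation.sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.29) < 0.02

    def test_reproducible_with_fixed_seed(self):
        a1, t1 = simulate_genome(n_operons=10, n_srnas=3, n_decoys=2, n_known_srnas=2, n_spurious_predictions=1, seed=5)
        a2, t2 = simulate_genome(n_operons=10, n_srnas=3, n_decoys=2, n_known_srnas=2, n_spurious_predictions=1, seed=5)
        assert a1.sequence == a2.sequence
        assert t1.to_frame().equals(t2.to_frame())

    def test_zero_srnas_gives_no_true_rows(self):
        _, truth = simulate_genome(n_srnas=0, n_decoys=2, seed=6)
        assert truth.of_class("srna_true") == []

    def test_hfq_fraction_realized_exactly(self, synthetic_dataset):
        _, truth, _, _ = synthetic_dataset
        srnas = truth.of_class("srna_true")
        assert sum(r.hfq_positive for r in srnas) == round(0.5 * len(srnas))

    def test_planted_srnas_lie_inside_iors_with_flank_clearance(self, synthetic_dataset):
        annotation, truth, _, _ = synthetic_dataset
        iors = derive_iors(annotation)
        for rec in truth.of_class("srna_true"):
            home = [r for r in iors if r.start <= rec.start and rec.end <= r.end]
            assert len(home) == 1
            (ior,) = home
            (ls, le), (rs, _) = flank_windows(ior, 50)
            assert rec.start >= le and rec.end <= rs

    def test_decoys_abut_an_orf_boundary(self, synthetic_dataset):
        annotation, truth, _, _ = synthetic_dataset
        ends = {f.end for f in annotation.orfs}
        starts = {f.start for f in annotation.orfs}
        for rec in truth.of_class("utr_decoy"):
            assert (rec.decoy_side == "left" and rec.start in ends) or (
                rec.decoy_side == "right" and rec.end in starts
            )

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            simulate_genome(n_operons=3, n_srnas=10, seed=7)


class TestEffects:
    def _record(self, direction):
        return TruthRecord(
            feature_id="s",
            klass="srna_true",
            start=0,
            end=100,
            strand="+",
            baseline_mean=100.0,
            direction=direction,
            responsive_to=("butanol",),
            hfq_positive=False,
            has_terminator=False,
        )

    def test_no_stress_effect_is_one(self):
        assert self._record(1).effect("none", "none", 30) == 1.0

    def test_monotone_in_dose(self):
        rec = self._record(1)
        effects = [rec.effect("butanol", d, 60) for d in ("low", "medium", "high")]
        assert effects == sorted(effects) and effects[0] > 1

    def test_down_regulation_is_reciprocal(self):
        up = self._record(1).effect("butanol", "high", 60)
        down = self._record(-1).effect("butanol", "high", 60)
        assert down == pytest.approx(1 / up)

    def test_unresponsive_stressor_leaves_effect_one(self):
        assert self._record(1).effect("butyrate", "high", 60) == 1.0


class TestCounts:
    def test_reproducible_with_fixed_seed(self):
        annotation, truth = simulate_genome(n_operons=10, n_srnas=3, n_decoys=2, n_known_srnas=2, n_spurious_predictions=1, seed=5)
        design = StudyDesign.default(n_replicates=1)
        r1 = simulate_counts(design, truth, annotation, depth=5000, seed=9)
        r2 = simulate_counts(design, truth, annotation, depth=5000, seed=9)
        for lib in r1:
            assert (r1[lib].starts == r2[lib].starts).all()

    def test_zero_depth_gives_empty_readsets(self):
        annotation, truth = simulate_genome(n_operons=10, n_srnas=3, n_decoys=2, n_known_srnas=2, n_spurious_predictions=1, seed=5)
        design = StudyDesign.default(n_replicates=1)
        readsets = simulate_counts(design, truth, annotation, depth=0, seed=9)
        assert all(len(rs) == 0 for rs in readsets.values())

    def test_dispersion_zero_degenerates_to_poisson(self):
        """Sample variance/mean of a mu=500 feature across replicate draws ~ 1."""
        rng_draws = []
        annotation, truth = simulate_genome(
            n_operons=4, n_srnas=1, n_decoys=0, n_known_srnas=0,
            n_structural=0, n_spurious_predictions=0, seed=11,
        )
        # isolate the sRNA: count its reads over 200 replicate libraries
        rec = truth.of_class("srna_true")[0]
        from srnome.quantify import count_reads
        import pandas as pd

        features = pd.DataFrame(
            {"feature_id": ["s"], "start": [rec.start], "end": [rec.end]}
        )
        base = sum(r.baseline_mean for r in truth.records)
        depth = int(base)  # scale factor 1: mu equals baseline
        design = StudyDesign(
            libraries=[
                StudyDesign.default(1).libraries[0].__class__(
                    library_id=f"l{i}", condition_id="control", stressor="none",
                    dose="none", dose_mM=0.0, time_min=15, replicate=i + 1,
                )
                for i in range(200)
            ]
        )
        readsets = simulate_counts(
            design, truth, annotation, dispersion=0.0, depth=depth,
            noise_rate=0.0, size_factor_sigma=0.0, seed=12,
        )
        for rs in readsets.values():
            rng_draws.append(count_reads(rs, features).iloc[0])
        draws = np.array(rng_draws, dtype=float)
        ratio = draws.var(ddof=1) / draws.mean()
        assert 0.8 < ratio < 1.2

    def test_mean_counts_converge_to_expectation(self):
        """Empirical per-feature means track mu * effect within 5% at many reps."""
        annotation, truth = simulate_genome(
            n_operons=4, n_srnas=2, n_decoys=0, n_known_srnas=0,
            n_structural=0, n_spurious_predictions=0, seed=21,
        )
        import pandas as pd
        from srnome.quantify import count_reads

        rec = max(truth.of_class("srna_true"), key=lambda r: r.baseline_mean)
        features = pd.DataFrame(
            {"feature_id": ["s"], "start": [rec.start], "end": [rec.end]}
        )
        base = sum(r.baseline_mean for r in truth.records)
        depth = int(base)
        design = StudyDesign(
            libraries=[
                StudyDesign.default(1).libraries[0].__class__(
                    library_id=f"l{i}", condition_id="control", stressor="none",
                    dose="none", dose_mM=0.0, time_min=15, replicate=i + 1,
                )
                for i in range(500)
            ]
        )
        readsets = simulate_counts(
            design, truth, annotation, dispersion=0.05, depth=depth,
            noise_rate=0.0, size_factor_sigma=0.0, seed=22,
        )
        means = np.array(
            [count_reads(rs, features).iloc[0] for rs in readsets.values()],
            dtype=float,
        )
        expected = rec.baseline_mean * depth / base
        assert abs(means.mean() - expected) / expected < 0.05

    def test_decoy_reads_stay_within_window_plus_read_length(self, synthetic_dataset):
        annotation, truth, design, readsets = synthetic_dataset
        decoys = truth.of_class("utr_decoy")
        lo = {r.feature_id: r.start - 49 for r in decoys}
        hi = {r.feature_id: r.end + 49 for r in decoys}
        # decoy reads are identifiable by construction: they overlap the window
        # but we check the invariant on the coverage side instead
        from srnome.quantify import summed_coverage
        from srnome.annotation import IOR

        all_rs = list(readsets.values())
        for rec in decoys:
            if rec.decoy_side == "left":
                region = IOR("x", rec.end, rec.end + 200)
            else:
                region = IOR("x", rec.start - 200, rec.start)
            # beyond 49 nt from the window only background noise remains
            cov = summed_coverage(all_rs, region)
            far = cov[49 + 60 :] if rec.decoy_side == "left" else cov[: -(49 + 60)]
            assert far.max() <= 10  # noise-level only
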