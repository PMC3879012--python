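"""Differential expression under graded stress, ratio matrices, clustering.

The test machinery follows the classic count-based DE recipe: per-library size
factors by the median-of-ratios estimator, a two-group negative-binomial test
by exact conditional enumeration on the group sums (normal approximation for
very large totals), and a method-of-moments dispersion estimate. Differential
calls use the raw p <= alpha rule (no multiple-testing correction by default;
an optional Benjamini-Hochberg flag is provided), pairwise per time point
against the no-stress control.

Expression-pattern analysis builds log2 ratio matrices of normalized stress
vs. matched-time control means, hierarchically clusters them (Pearson
correlation distance, average linkage by default), and ranks each feature's
abundance within each library as a 0-100 percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .quantify import CountMatrix
from .simulate import StudyDesign

log = logging.getLogger(__name__)

EXACT_TOTAL_MAX = 10_000


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    ``factor_l = median_f count_{f,l} / geomean_f`` over features with nonzero
    counts in every library; if no such feature exists, falls back (logged) to
    the median over features nonzero in that library.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        sub = mat[all_pos]
        gm = np.exp(np.log(sub).mean(axis=1))
        factors = np.median(sub / gm[:, None], axis=0)
    else:
        log.warning("no feature nonzero in all libraries; per-library fallback")
        factors = np.empty(mat.shape[1])
        log_gm = np.log(np.where(mat > 0, mat, np.nan))
        log_gm = np.nanmean(log_gm, axis=1)
        for j in range(mat.shape[1]):
            pos = mat[:, j] > 0
            if not pos.any():
                factors[j] = 1.0
                continue
            factors[j] = np.exp(
                np.median(np.log(mat[pos, j]) - log_gm[pos])
            )
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise ValueError("size factors must be positive and finite")
    return pd.Series(factors, index=counts.columns, name="size_factor")


# --------------------------------------------------------------------------
# Negative-binomial two-group test
# --------------------------------------------------------------------------

def _group_pmf(k: np.ndarray, mu: float, var: float) -> np.ndarray:
    if mu <= 0:
        out = np.zeros_like(k, dtype=float)
        out[k == 0] = 1.0
        return out
    if var <= mu * (1 + 1e-12):
        return stats.poisson.pmf(k, mu)
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return stats.nbinom.pmf(k, r, p)


def nb_test(
    counts_control: np.ndarray,
    counts_stress: np.ndarray,
    sf_control: np.ndarray,
    sf_stress: np.ndarray,
    dispersion: float,
) -> float:
    """Two-sided p-value for equal normalized means under the NB model.

    Conditions on the total of the two group sums: with the common normalized
    mean estimated from the pooled data, the probability of every split
    ``(a, total - a)`` is evaluated and the p-value is the summed probability
    of splits no more likely than the observed one (the min-likelihood
    two-sided rule), normalized over all splits. Exact enumeration is used for
    totals up to 10^4 and a conditional normal approximation beyond that. The
    statistic is symmetric in group order, and at dispersion 0 it reduces to
    the conditional binomial test.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    ka = int(np.sum(counts_control))
    kb = int(np.sum(counts_stress))
    total = ka + kb
    if total == 0:
        return 1.0
    sa = float(np.sum(sf_control))
    sb = float(np.sum(sf_stress))
    q = total / (sa + sb)
    mu_a, mu_b = q * sa, q * sb
    var_a = mu_a + dispersion * q * q * float(np.sum(np.square(sf_control)))
    var_b = mu_b + dispersion * q * q * float(np.sum(np.square(sf_stress)))

    if total <= EXACT_TOTAL_MAX:
        a = np.arange(total + 1)
        joint = _group_pmf(a, mu_a, var_a) * _group_pmf(total - a, mu_b, var_b)
        denom = joint.sum()
        if denom <= 0:
            return 1.0
        p_obs = joint[ka]
        p = joint[joint <= p_obs * (1 + 1e-10)].sum() / denom
        return float(min(1.0, p))

    # conditional normal approximation on K_A | K_A + K_B = total
    w = var_a / (var_a + var_b)
    mean_cond = mu_a + (total - mu_a - mu_b) * w
    var_cond = var_a * var_b / (var_a + var_b)
    z = (ka - mean_cond) / np.sqrt(var_cond)
    return float(min(1.0, 2 * stats.norm.sf(abs(z))))


# --------------------------------------------------------------------------
# Dispersion estimation
# --------------------------------------------------------------------------

def _replicate_groups(design: StudyDesign) -> dict[tuple, list[str]]:
    groups: dict[tuple, list[str]] = {}
    for lib in design.libraries:
        groups.setdefault((lib.condition_id, lib.time_min), []).append(lib.library_id)
    return groups


def estimate_dispersion(
    matrix: CountMatrix,
    design: StudyDesign,
    min_dispersion: float = 0.01,
    factors: pd.Series | None = None,
) -> pd.Series:
    """Per-feature method-of-moments dispersion, pooled across replicate groups.

    On normalized counts, ``alpha_raw = (pooled within-group variance - pooled
    mean) / pooled mean^2`` per feature, truncated at 0 and floored at
    ``min_dispersion``. Designs without any replicated group fall back to a
    global default (logged).
    """
    if factors is None:
        factors = size_factors(matrix.counts)
    norm = matrix.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    cols = {c: j for j, c in enumerate(matrix.counts.columns)}
    groups = [
        [cols[l] for l in libs if l in cols]
        for libs in _replicate_groups(design).values()
    ]
    groups = [g for g in groups if len(g) >= 2]
    if not groups:
        log.warning("no replicated groups; using global fallback dispersion")
        return pd.Series(
            min_dispersion, index=matrix.counts.index, name="dispersion"
        )
    ss = np.zeros(norm.shape[0])
    df_total = 0
    mean_acc = np.zeros(norm.shape[0])
    n_groups = 0
    for g in groups:
        sub = norm[:, g]
        ss += sub.var(axis=1, ddof=1) * (len(g) - 1)
        df_total += len(g) - 1
        mean_acc += sub.mean(axis=1)
        n_groups += 1
    s2 = ss / df_total
    mu = mean_acc / n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (s2 - mu) / (mu * mu), 0.0)
    alpha = np.maximum(np.maximum(raw, 0.0), min_dispersion)
    return pd.Series(alpha, index=matrix.counts.index, name="dispersion")


def pooled_dispersion(
    matrix: CountMatrix,
    design: StudyDesign,
    min_dispersion: float = 0.001,
    factors: pd.Series | None = None,
) -> float:
    """One shared dispersion: ratio-of-means method-of-moments across features.

    ``alpha = mean_f(s2_f - mu_f) / mean_f(mu_f^2)`` using within-replicate-
    group moments; sharing across features stabilizes the estimate at the
    2-3 replicates typical of these designs.
    """
    if factors is None:
        factors = size_factors(matrix.counts)
    norm = matrix.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    cols = {c: j for j, c in enumerate(matrix.counts.columns)}
    groups = [
        [cols[l] for l in libs if l in cols]
        for libs in _replicate_groups(design).values()
    ]
    groups = [g for g in groups if len(g) >= 2]
    if not groups:
        log.warning("no replicated groups; using fallback dispersion")
        return max(min_dispersion, 0.01)
    num = 0.0
    den = 0.0
    for g in groups:
        sub = norm[:, g]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        keep = mu > 0
        num += float((s2[keep] - mu[keep]).sum())
        den += float((mu[keep] ** 2).sum())
    if den <= 0:
        return max(min_dispersion, 0.01)
    return max(num / den, min_dispersion)


# --------------------------------------------------------------------------
# Pairwise DE vs control
# --------------------------------------------------------------------------

def call_de(
    matrix: CountMatrix,
    design: StudyDesign,
    alpha: float = 0.05,
    dispersion: float | pd.Series | None = None,
    features: list[str] | None = None,
    bh_correct: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pairwise NB tests of each stress (stressor, dose) vs control, per time point.

    Returns one row per (feature, stressor, dose, time) with normalized group
    means, log2 ratio (with pseudocount), p-value and the significance flag at
    ``alpha``. ``dispersion=None`` uses the pooled across-feature estimate; a
    scalar or per-feature Series may be supplied instead. ``bh_correct``
    switches the flag to Benjamini-Hochberg-adjusted p-values (off by default,
    matching the raw-p thresholding convention of the original analysis).
    """
    factors = size_factors(matrix.counts)
    if dispersion is None:
        dispersion = pooled_dispersion(matrix, design, factors=factors)
    sub = matrix.counts if features is None else matrix.counts.loc[features]

    libs = design.to_frame().set_index("library_id")
    control_by_time: dict[int, list[str]] = {}
    for lib_id, row in libs.iterrows():
        if row["stressor"] == "none":
            control_by_time.setdefault(int(row["time_min"]), []).append(lib_id)

    contrasts = sorted(
        {
            (row["stressor"], row["dose"], int(row["time_min"]))
            for _, row in libs.iterrows()
            if row["stressor"] != "none"
        },
        key=lambda c: (c[0], ("low", "medium", "high").index(c[1]), c[2]),
    )

    rows = []
    for stressor, dose, t in contrasts:
        ctrl_libs = control_by_time.get(t, [])
        if not ctrl_libs:
            log.warning("no control libraries at t=%d; contrast skipped", t)
            continue
        stress_libs = [
            l
            for l, row in libs.iterrows()
            if row["stressor"] == stressor
            and row["dose"] == dose
            and int(row["time_min"]) == t
        ]
        sf_c = factors[ctrl_libs].to_numpy()
        sf_s = factors[stress_libs].to_numpy()
        kc = sub[ctrl_libs].to_numpy()
        ks = sub[stress_libs].to_numpy()
        mean_c = (kc / sf_c[None, :]).mean(axis=1)
        mean_s = (ks / sf_s[None, :]).mean(axis=1)
        log2_ratio = np.log2((mean_s + pseudocount) / (mean_c + pseudocount))
        for i, fid in enumerate(sub.index):
            disp = (
                float(dispersion[fid])
                if isinstance(dispersion, pd.Series)
                else float(dispersion)
            )
            p = nb_test(kc[i], ks[i], sf_c, sf_s, disp)
            rows.append(
                {
                    "feature_id": fid,
                    "stressor": stressor,
                    "dose": dose,
                    "time_min": t,
                    "mean_control": mean_c[i],
                    "mean_stress": mean_s[i],
                    "log2_ratio": log2_ratio[i],
                    "p_value": p,
                }
            )
    de = pd.DataFrame(rows)
    if de.empty:
        de["significant"] = []
        de["direction"] = []
        return de
    if bh_correct:
        de["p_adjusted"] = _bh_adjust(de["p_value"].to_numpy())
        de["significant"] = de["p_adjusted"] <= alpha
    else:
        de["significant"] = de["p_value"] <= alpha
    de["direction"] = np.where(
        de["significant"], np.where(de["log2_ratio"] > 0, "up", "down"), ""
    )
    return de


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_summary(de: pd.DataFrame) -> pd.DataFrame:
    """Up/down significant-feature counts per stress level (any time point)."""
    if de.empty:
        return pd.DataFrame(columns=["stressor", "dose", "n_up", "n_down"])
    rows = []
    for (stressor, dose), grp in de.groupby(["stressor", "dose"], sort=False):
        sig = grp[grp["significant"]]
        rows.append(
            {
                "stressor": stressor,
                "dose": dose,
                "n_up": sig.loc[sig["direction"] == "up", "feature_id"].nunique(),
                "n_down": sig.loc[sig["direction"] == "down", "feature_id"].nunique(),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Ratio matrices, clustering, percentile ranks
# --------------------------------------------------------------------------

def ratio_matrix(
    matrix: CountMatrix,
    design: StudyDesign,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """log2 normalized stress/control mean ratio per (stressor, dose, time).

    Columns are labelled ``stressor:dose:tNN``; the control is the matched
    time point of the no-stress condition.
    """
    if factors is None:
        factors = size_factors(matrix.counts)
    sub = matrix.counts if features is None else matrix.counts.loc[features]
    norm = sub / factors
    libs = design.to_frame().set_index("library_id")
    control_by_time = {
        t: [l for l, r in libs.iterrows() if r["stressor"] == "none" and r["time_min"] == t]
        for t in sorted(libs["time_min"].unique())
    }
    cols = {}
    contrasts = sorted(
        {
            (r["stressor"], r["dose"], int(r["time_min"]))
            for _, r in libs.iterrows()
            if r["stressor"] != "none"
        },
        key=lambda c: (c[0], ("low", "medium", "high").index(c[1]), c[2]),
    )
    for stressor, dose, t in contrasts:
        ctrl = control_by_time.get(t, [])
        if not ctrl:
            continue
        stress_libs = [
            l
            for l, r in libs.iterrows()
            if r["stressor"] == stressor and r["dose"] == dose and r["time_min"] == t
        ]
        m_s = norm[stress_libs].mean(axis=1)
        m_c = norm[ctrl].mean(axis=1)
        cols[f"{stressor}:{dose}:t{t}"] = np.log2(
            (m_s + pseudocount) / (m_c + pseudocount)
        )
    return pd.DataFrame(cols, index=sub.index)


@dataclass
class ClusterResult:
    ratio_matrix: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series
    leaf_order: list[str]
    newick: str


def _correlation_distance(mat: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r with a zero-variance guard (distance 1)."""
    n = mat.shape[0]
    sd = mat.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant rows: correlation distance set to 1", constant.sum())
    centered = mat - mat.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * mat.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = centered @ centered.T / denom
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick tree string."""
    n = len(labels)

    def node(i: int) -> tuple[str, float]:
        if i < n:
            return labels[i], 0.0
        a, b, height, _ = Z[i - n]
        sa, ha = node(int(a))
        sb, hb = node(int(b))
        return f"({sa}:{height - ha:.6g},{sb}:{height - hb:.6g})", float(height)

    s, _ = node(2 * n - 2) if n > 1 else (labels[0], 0.0)
    return s + ";"


def hcluster(
    ratio_block: pd.DataFrame,
    distance: str = "correlation",
    linkage_method: str = "average",
    k: int | None = 4,
    height: float | None = None,
) -> ClusterResult:
    """Agglomerative clustering of a feature x contrast ratio matrix.

    Default distance is 1 - Pearson correlation with a zero-variance guard;
    linkage is average. The tree is cut at ``k`` clusters (or at ``height``).
    SciPy's linkage resolves equal-distance merges by lowest index, so the
    result is deterministic for a given row order; cluster membership is
    invariant to row permutation up to relabeling.
    """
    if ratio_block.isna().all(axis=1).any():
        raise ValueError("ratio matrix contains all-missing rows")
    mat = ratio_block.to_numpy(dtype=float)
    if mat.shape[0] < 2:
        labels = pd.Series(np.ones(mat.shape[0], dtype=int), index=ratio_block.index)
        return ClusterResult(ratio_block, np.empty((0, 4)), labels, list(ratio_block.index), "();")
    if distance == "correlation":
        dist = squareform(_correlation_distance(mat), checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        dist = pdist(mat)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Z = hierarchy.linkage(dist, method=linkage_method)
    if height is not None:
        labels = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        labels = hierarchy.fcluster(Z, t=k or 4, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    return ClusterResult(
        ratio_matrix=ratio_block,
        linkage=Z,
        labels=pd.Series(labels, index=ratio_block.index, name="cluster"),
        leaf_order=[ratio_block.index[i] for i in order],
        newick=linkage_to_newick(Z, list(ratio_block.index)),
    )


def percentile_rank(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Within-library abundance percentile of each feature, 0-100.

    Normalized counts are ranked ascending; rank r of n maps to
    ``100 * (r - 1) / (n - 1)`` with ties given the mean of their positions'
    percentiles. A single-feature matrix ranks 100 by convention.
    """
    if factors is None:
        factors = size_factors(counts)
    norm = counts / factors
    n = norm.shape[0]
    if n == 1:
        log.warning("single feature: percentile rank 100 by convention")
        return pd.DataFrame(
            100.0, index=counts.index, columns=counts.columns
        )
    ranks = norm.apply(lambda col: stats.rankdata(col, method="average"), axis=0)
    return ((ranks - 1) * (100.0 / (n - 1))).clip(0.0, 100.0)
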