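"""Simulation-based calibration checks for the NB differential-expression test.

These drive the null type-I-error and planted-effect power studies that
validate the test machinery: counts are drawn from the same NB family the test
assumes (variance ``mu + alpha mu^2``), with lognormal library size factors,
and analyzed exactly as the pipeline would (median-of-ratios size factors,
pooled method-of-moments dispersion, exact conditional NB test).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import CountMatrix
from .simulate import Library, StudyDesign
from .stresscompare import nb_test, pooled_dispersion, size_factors


def _two_group_design(n_reps: int) -> StudyDesign:
    libs = []
    for grp, stressor, dose, mm in (
        ("control", "none", "none", 0.0),
        ("butanol_high", "butanol", "high", 90.0),
    ):
        for r in range(1, n_reps + 1):
            libs.append(
                Library(
                    library_id=f"{grp}_r{r}",
                    condition_id=grp,
                    stressor=stressor,
                    dose=dose,
                    dose_mM=mm,
                    time_min=30,
                    replicate=r,
                )
            )
    return StudyDesign(libraries=libs)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + np.where(mu > 0, mu, 1.0))
    return np.where(mu > 0, rng.negative_binomial(r, p), 0)


def simulate_two_group_matrix(
    n_features: int,
    mu: np.ndarray | float,
    fold_change: np.ndarray | float,
    dispersion: float,
    n_reps: int,
    seed: int,
    size_factor_sigma: float = 0.15,
) -> tuple[CountMatrix, StudyDesign]:
    """Control vs stress count matrix with per-feature fold changes."""
    rng = np.random.default_rng(seed)
    design = _two_group_design(n_reps)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n_features,))
    fold = np.broadcast_to(np.asarray(fold_change, dtype=float), (n_features,))
    cols = {}
    for lib in design.libraries:
        s = float(rng.lognormal(0.0, size_factor_sigma))
        m = mu * s * np.where(lib.stressor != "none", fold, 1.0)
        cols[lib.library_id] = _nb_draw(rng, m, dispersion)
    counts = pd.DataFrame(cols)
    counts.index = [f"F{i:05d}" for i in range(n_features)]
    classes = pd.Series("ior", index=counts.index)
    return CountMatrix(counts=counts, classes=classes), design


def null_rejection_rate(
    n_features: int = 2000,
    mu: float = 200.0,
    dispersion: float = 0.05,
    n_reps: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of null (equal-mean) features rejected at level ``alpha``.

    Returns the observed rate and its 3-standard-error band around ``alpha``
    under the binomial model.
    """
    matrix, design = simulate_two_group_matrix(
        n_features, mu, 1.0, dispersion, n_reps, seed
    )
    factors = size_factors(matrix.counts)
    disp = pooled_dispersion(matrix, design, factors=factors)
    libs = design.to_frame()
    ctrl = libs.loc[libs.stressor == "none", "library_id"].tolist()
    stress = libs.loc[libs.stressor != "none", "library_id"].tolist()
    sf_c = factors[ctrl].to_numpy()
    sf_s = factors[stress].to_numpy()
    kc = matrix.counts[ctrl].to_numpy()
    ks = matrix.counts[stress].to_numpy()
    pvals = np.array(
        [nb_test(kc[i], ks[i], sf_c, sf_s, disp) for i in range(n_features)]
    )
    rate = float((pvals <= alpha).mean())
    se = float(np.sqrt(alpha * (1 - alpha) / n_features))
    return {
        "rate": rate,
        "alpha": alpha,
        "se": se,
        "lo": alpha - 3 * se,
        "hi": alpha + 3 * se,
        "dispersion_estimate": disp,
    }


def planted_effect_power(
    fold_change: float = 4.0,
    mu: float = 200.0,
    dispersion: float = 0.05,
    n_reps: int = 3,
    n_repeats: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_null_features: int = 200,
) -> dict[str, float]:
    """Detection power and sign accuracy for a planted fold change.

    Each repeat simulates one affected feature alongside null features (which
    anchor size factors and the pooled dispersion) and tests it. Power is the
    fraction of repeats with p <= alpha; direction accuracy is the fraction of
    those with a positive log2 ratio for ``fold_change > 1``.
    """
    rng = np.random.default_rng(seed)
    detected = 0
    correct_sign = 0
    for _ in range(n_repeats):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fold = np.ones(n_null_features + 1)
        fold[0] = fold_change
        matrix, design = simulate_two_group_matrix(
            n_null_features + 1, mu, fold, dispersion, n_reps, sub_seed
        )
        libs = design.to_frame()
        ctrl = libs.loc[libs.stressor == "none", "library_id"].tolist()
        stress = libs.loc[libs.stressor != "none", "library_id"].tolist()
        factors = size_factors(matrix.counts)
        disp = pooled_dispersion(matrix, design, factors=factors)
        kc = matrix.counts.loc["F00000", ctrl].to_numpy()
        ks = matrix.counts.loc["F00000", stress].to_numpy()
        p = nb_test(kc, ks, factors[ctrl].to_numpy(), factors[stress].to_numpy(), disp)
        if p <= alpha:
            detected += 1
            mean_c = (kc / factors[ctrl].to_numpy()).mean()
            mean_s = (ks / factors[stress].to_numpy()).mean()
            if (mean_s > mean_c) == (fold_change > 1):
                correct_sign += 1
    return {
        "power": detected / n_repeats,
        "sign_accuracy": correct_sign / max(detected, 1),
        "n_repeats": n_repeats,
    }
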