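"""Novel-sRNA calling: threshold, prediction intersection, UTR filter, naming.

The procedure mirrors a three-stage screen over interoperonic regions (IORs):

1. **Expression threshold** — an IOR is expressed when its raw read count
   reaches ``min_count`` (default 50) in a quorum of libraries (default: any
   single library, the permissive reading that keeps condition-specific sRNAs).
2. **Prediction intersection** — expressed IORs must contain at least one
   computationally predicted sRNA interval (>= 1 nt overlap); predictions that
   rediscover already-known sRNAs are excluded.
3. **UTR false-positive filter** — candidates whose coverage is predominantly
   in the flank windows abutting an *expressed* neighboring ORF are eliminated
   as UTR bleed: coverage share of the two flank windows >= ``dominance`` AND
   the neighbor ORF on the dominant side has count >= ``neighbor_min``.

Survivors are named ``sCAC<n>`` after the locus number of the nearest
downstream ORF (the right neighbor, falling back to the left at the contig
end), with deterministic a/b suffixes when several survivors share a
reference ORF.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import IOR, Feature, GenomeAnnotation, flank_windows
from .quantify import CountMatrix

log = logging.getLogger(__name__)

STATUS_NOT_EXPRESSED = "not_expressed"
STATUS_NO_PREDICTION = "expressed_no_prediction"
STATUS_FP_UTR = "fp_utr"
STATUS_NOVEL = "novel_srna"


@dataclass
class CandidateCall:
    """One IOR's passage through the calling pipeline."""

    ior_id: str
    qualifying_count: int  # max per-library count
    n_libraries_passing: int
    passed_threshold: bool
    predictions_in_ior: tuple[str, ...] = ()
    utr_left_fraction: float = 0.0
    utr_right_fraction: float = 0.0
    neighbor_left_count: int = 0
    neighbor_right_count: int = 0
    status: str = STATUS_NOT_EXPRESSED
    assigned_name: str | None = None
    needs_review: bool = False

    def validate(self) -> None:
        if self.status == STATUS_NOVEL:
            assert self.passed_threshold and self.predictions_in_ior
        for frac in (self.utr_left_fraction, self.utr_right_fraction):
            assert 0.0 <= frac <= 1.0


def call_expressed_iors(
    matrix: CountMatrix,
    min_count: int = 50,
    min_library_fraction: float | None = None,
) -> list[str]:
    """IOR ids whose count reaches ``min_count`` in enough libraries.

    The quorum is ``ceil(min_library_fraction * n_libraries)``; when the
    fraction is None a single library suffices.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    iors = matrix.subset("ior")
    n_libs = iors.shape[1]
    quorum = (
        1
        if min_library_fraction is None
        else max(1, math.ceil(min_library_fraction * n_libs))
    )
    passing = (iors >= min_count).sum(axis=1)
    return list(iors.index[passing >= quorum])


def intersect_predictions(
    expressed_ior_ids: list[str],
    iors: list[IOR],
    predicted_srnas: list[Feature],
    excluded_prediction_ids: set[str] = frozenset(),
) -> dict[str, tuple[str, ...]]:
    """Predicted-sRNA ids overlapping (>= 1 nt) each expressed IOR.

    ``excluded_prediction_ids`` removes predictions that correspond to
    already-known sRNAs so they are not counted as novel.
    """
    tree = IntervalTree()
    for p in predicted_srnas:
        if p.feature_id not in excluded_prediction_ids:
            tree[p.start : p.end] = p.feature_id
    by_id = {r.ior_id: r for r in iors}
    out: dict[str, tuple[str, ...]] = {}
    for ior_id in expressed_ior_ids:
        r = by_id[ior_id]
        hits = sorted(iv.data for iv in tree[r.start : r.end])
        out[ior_id] = tuple(hits)
    return out


def known_prediction_ids(
    predicted_srnas: list[Feature], known_srnas: list[Feature]
) -> set[str]:
    """Ids of predictions that overlap a known sRNA (the exclusion list)."""
    tree = IntervalTree()
    for k in known_srnas:
        tree[k.start : k.end] = k.feature_id
    return {p.feature_id for p in predicted_srnas if tree[p.start : p.end]}


@dataclass
class UtrFilterResult:
    is_fp: bool
    left_fraction: float
    right_fraction: float
    needs_review: bool


def utr_fp_filter(
    ior: IOR,
    coverage: np.ndarray,
    neighbor_counts: tuple[int, int],
    w: int = 50,
    dominance: float = 0.8,
    neighbor_min: int = 50,
) -> UtrFilterResult:
    """Flag a candidate whose coverage is UTR bleed from an expressed neighbor.

    The candidate is a false positive iff the coverage share of the two
    ``w``-nt flank windows reaches ``dominance`` *and* the neighbor ORF on the
    dominant side is itself expressed (count >= ``neighbor_min``). IORs no
    longer than ``w`` cannot be meaningfully tested (the window is the whole
    region); they are retained and flagged for review.
    """
    if len(coverage) != len(ior):
        raise ValueError("coverage length must equal IOR length")
    total = float(coverage.sum())
    if len(ior) <= w:
        return UtrFilterResult(False, 1.0 if total else 0.0, 1.0 if total else 0.0, True)
    if total == 0:
        return UtrFilterResult(False, 0.0, 0.0, False)
    (ls, le), (rs, re_) = flank_windows(ior, w)
    left = float(coverage[: le - ior.start].sum()) / total
    right = float(coverage[rs - ior.start :].sum()) / total
    # union share, not double counting any window overlap
    lo = max(ls, rs)
    overlap = (
        float(coverage[lo - ior.start : le - ior.start].sum()) / total if lo < le else 0.0
    )
    share = left + right - overlap
    nb_left, nb_right = neighbor_counts
    dominant_nb = nb_left if left >= right else nb_right
    is_fp = share >= dominance and dominant_nb >= neighbor_min
    return UtrFilterResult(is_fp, left, right, False)


_LOCUS_RE = re.compile(r"(\d+)$")


def name_candidates(
    survivor_iors: list[IOR], annotation: GenomeAnnotation
) -> dict[str, str]:
    """Deterministic sCAC<n> names from the nearest downstream ORF locus number.

    ``n`` is the numeric suffix of the right-neighbor ORF id (left neighbor at
    the contig end); several survivors sharing a reference ORF are suffixed
    a, b, ... in genomic order.
    """
    refs: list[tuple[str, int, int]] = []  # (ior_id, locus_number, start)
    for ior in sorted(survivor_iors, key=lambda r: r.start):
        ref = ior.right_neighbor or ior.left_neighbor
        if ref is None:
            log.warning("survivor %s has no neighboring ORF; skipped", ior.ior_id)
            continue
        m = _LOCUS_RE.search(ref)
        if not m:
            raise ValueError(f"cannot extract locus number from ORF id {ref!r}")
        refs.append((ior.ior_id, int(m.group(1)), ior.start))
    by_locus: dict[int, list[tuple[str, int]]] = {}
    for ior_id, locus, start in refs:
        by_locus.setdefault(locus, []).append((ior_id, start))
    names: dict[str, str] = {}
    for locus, members in by_locus.items():
        members.sort(key=lambda t: t[1])
        if len(members) == 1:
            names[members[0][0]] = f"sCAC{locus}"
        else:
            for suffix, (ior_id, _) in zip("abcdefghij", members):
                names[ior_id] = f"sCAC{locus}{suffix}"
    return names


def run_discovery(
    matrix: CountMatrix,
    coverage_by_ior: dict[str, np.ndarray],
    iors: list[IOR],
    annotation: GenomeAnnotation,
    min_count: int = 50,
    min_library_fraction: float | None = None,
    flank_w: int = 50,
    dominance: float = 0.8,
    neighbor_min: int = 50,
) -> pd.DataFrame:
    """Full candidate ledger: one row per IOR with every intermediate field."""
    ior_counts = matrix.subset("ior")
    expressed = set(
        call_expressed_iors(matrix, min_count, min_library_fraction)
    )
    excluded = known_prediction_ids(
        annotation.predicted_srnas, annotation.known_srnas
    )
    preds = intersect_predictions(
        sorted(expressed), iors, annotation.predicted_srnas, excluded
    )
    orf_counts = matrix.counts.loc[matrix.classes.isin(["orf", "structural"])]
    orf_max = orf_counts.max(axis=1) if not orf_counts.empty else pd.Series(dtype=float)

    calls: list[CandidateCall] = []
    survivors: list[IOR] = []
    by_id = {r.ior_id: r for r in iors}
    for ior_id in ior_counts.index:
        ior = by_id[ior_id]
        row = ior_counts.loc[ior_id]
        n_pass = int((row >= min_count).sum())
        call = CandidateCall(
            ior_id=ior_id,
            qualifying_count=int(row.max()),
            n_libraries_passing=n_pass,
            passed_threshold=ior_id in expressed,
        )
        nb_left = int(orf_max.get(ior.left_neighbor, 0)) if ior.left_neighbor else 0
        nb_right = int(orf_max.get(ior.right_neighbor, 0)) if ior.right_neighbor else 0
        call.neighbor_left_count = nb_left
        call.neighbor_right_count = nb_right
        if not call.passed_threshold:
            call.status = STATUS_NOT_EXPRESSED
        elif not preds.get(ior_id):
            call.status = STATUS_NO_PREDICTION
        else:
            call.predictions_in_ior = preds[ior_id]
            cov = coverage_by_ior.get(ior_id)
            if cov is None:
                raise KeyError(f"no coverage profile for expressed IOR {ior_id}")
            res = utr_fp_filter(
                ior, cov, (nb_left, nb_right), flank_w, dominance, neighbor_min
            )
            call.utr_left_fraction = res.left_fraction
            call.utr_right_fraction = res.right_fraction
            call.needs_review = res.needs_review
            if res.is_fp:
                call.status = STATUS_FP_UTR
            else:
                call.status = STATUS_NOVEL
                survivors.append(ior)
        call.validate()
        calls.append(call)

    names = name_candidates(survivors, annotation)
    ledger = pd.DataFrame(
        {
            "ior_id": [c.ior_id for c in calls],
            "start": [by_id[c.ior_id].start for c in calls],
            "end": [by_id[c.ior_id].end for c in calls],
            "max_count": [c.qualifying_count for c in calls],
            "n_libraries_passing": [c.n_libraries_passing for c in calls],
            "passed_threshold": [c.passed_threshold for c in calls],
            "predictions": [",".join(c.predictions_in_ior) for c in calls],
            "utr_left_fraction": [round(c.utr_left_fraction, 6) for c in calls],
            "utr_right_fraction": [round(c.utr_right_fraction, 6) for c in calls],
            "neighbor_left_count": [c.neighbor_left_count for c in calls],
            "neighbor_right_count": [c.neighbor_right_count for c in calls],
            "needs_review": [c.needs_review for c in calls],
            "status": [c.status for c in calls],
            "assigned_name": [names.get(c.ior_id, "") for c in calls],
        }
    )
    return ledger
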