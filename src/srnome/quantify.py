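"""Aggregate mapped-read intervals into feature counts and per-base coverage.

The counting rule is unstranded: a read increments every feature it overlaps by
at least ``min_overlap_frac`` of the read length (default one half). Reads are
fixed-length start intervals, which lets the qualifying read-start range for a
feature be computed in closed form and counted with two binary searches per
feature; the test suite checks this against an all-pairs brute-force oracle.

Raw, un-normalized counts are used for threshold calibration (the read-count
histograms); size-factor-normalized counts appear only downstream in the
differential-expression and ratio-matrix stages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import IOR

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("orf", "known_srna", "structural", "ior")


@dataclass
class ReadSet:
    """Mapped reads of one library as sorted start positions of fixed length."""

    library_id: str
    contig_id: str
    read_length: int
    starts: np.ndarray  # sorted int64

    def __post_init__(self) -> None:
        self.starts = np.sort(np.asarray(self.starts, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.starts)

    def to_bed(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.contig_id,
                "start": self.starts,
                "end": self.starts + self.read_length,
                "name": [f"{self.library_id}.{i}" for i in range(len(self.starts))],
                "score": 0,
                "strand": ".",
            }
        )

    @classmethod
    def from_bed(cls, library_id: str, df: pd.DataFrame, read_length: int) -> "ReadSet":
        return cls(
            library_id=library_id,
            contig_id=str(df["chrom"].iloc[0]) if len(df) else "contig",
            read_length=read_length,
            starts=df["start"].to_numpy(),
        )


@dataclass
class CountMatrix:
    """Feature x library integer counts plus a per-feature class label."""

    counts: pd.DataFrame  # rows: feature ids, cols: library ids
    classes: pd.Series  # index: feature ids, values in FEATURE_CLASSES

    def __post_init__(self) -> None:
        self.classes = self.classes.reindex(self.counts.index)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValueError("feature/library ids must be unique")
        unknown = set(self.classes.dropna()) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, klass: str) -> pd.DataFrame:
        return self.counts.loc[self.classes == klass]

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "class", self.classes)
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        classes = df.pop("class")
        return cls(counts=df.astype(np.int64), classes=classes)


def count_reads(
    readset: ReadSet,
    features: pd.DataFrame,
    min_overlap_frac: float = 0.5,
    contig_length: int | None = None,
) -> pd.Series:
    """Count reads per feature under the fractional-overlap rule.

    ``features`` needs columns ``feature_id``, ``start``, ``end``. A read
    qualifies for a feature iff its overlap is ``>= ceil(min_overlap_frac *
    read_length)`` bases; a read may increment several features. Reads falling
    outside the contig are dropped (logged).
    """
    if not 0 < min_overlap_frac <= 1:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    L = readset.read_length
    starts = readset.starts
    if contig_length is not None:
        ok = (starts >= 0) & (starts + L <= contig_length)
        if not ok.all():
            log.warning(
                "library %s: dropped %d reads outside the contig",
                readset.library_id,
                int((~ok).sum()),
            )
            starts = starts[ok]
    m = math.ceil(min_overlap_frac * L)
    fs = features["start"].to_numpy()
    fe = features["end"].to_numpy()
    # A read start r qualifies iff r in [start - L + m, end - m], provided the
    # feature is at least m long (otherwise the overlap can never reach m).
    lo = fs - L + m
    hi = fe - m
    n = np.searchsorted(starts, hi, side="right") - np.searchsorted(starts, lo, side="left")
    n = np.where((fe - fs) >= m, n, 0)
    return pd.Series(n.astype(np.int64), index=features["feature_id"].to_numpy(), name=readset.library_id)


def build_count_matrix(
    readsets: list[ReadSet],
    features: pd.DataFrame,
    min_overlap_frac: float = 0.5,
    contig_length: int | None = None,
) -> CountMatrix:
    """Count every library against a feature table with a ``class`` column."""
    cols = {
        rs.library_id: count_reads(rs, features, min_overlap_frac, contig_length)
        for rs in readsets
    }
    counts = pd.DataFrame(cols)
    classes = pd.Series(
        features["class"].to_numpy(), index=features["feature_id"].to_numpy()
    )
    return CountMatrix(counts=counts, classes=classes)


def coverage_profile(readset: ReadSet, ior: IOR) -> np.ndarray:
    """Per-base pileup of read intervals clipped to the IOR."""
    L = readset.read_length
    starts = readset.starts
    sel = starts[
        np.searchsorted(starts, ior.start - L, side="left") : np.searchsorted(
            starts, ior.end, side="left"
        )
    ]
    cov = np.zeros(len(ior), dtype=np.int64)
    if len(sel) == 0:
        return cov
    a = np.clip(sel - ior.start, 0, len(ior))
    b = np.clip(sel + L - ior.start, 0, len(ior))
    keep = b > a
    np.add.at(cov, a[keep], 1)
    ends = b[keep]
    dec = np.zeros(len(ior) + 1, dtype=np.int64)
    np.add.at(dec, ends, -1)
    cov = np.cumsum(cov + dec[:-1])
    return cov


def summed_coverage(readsets: list[ReadSet], ior: IOR) -> np.ndarray:
    total = np.zeros(len(ior), dtype=np.int64)
    for rs in readsets:
        total += coverage_profile(rs, ior)
    return total


DEFAULT_BIN_EDGES = (0, 10, 25, 50, 100, 250, 500, 1000, np.inf)


def readcount_histogram(
    matrix: CountMatrix,
    klass: str,
    bin_edges=DEFAULT_BIN_EDGES,
    agg: str = "max",
) -> tuple[pd.DataFrame, float]:
    """Frequency distribution of feature read counts for one class.

    ``agg`` collapses the library dimension ("max", "sum", "mean", or a library
    id). Returns the histogram table and the fraction of features reaching a
    count of at least 50 — the calibration quantity behind the "minimum 50"
    expression threshold.
    """
    sub = matrix.subset(klass)
    if sub.empty:
        return pd.DataFrame(columns=["bin_left", "bin_right", "n_features"]), float("nan")
    if agg in sub.columns:
        vec = sub[agg]
    elif agg == "max":
        vec = sub.max(axis=1)
    elif agg == "sum":
        vec = sub.sum(axis=1)
    elif agg == "mean":
        vec = sub.mean(axis=1)
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    edges = np.asarray(bin_edges, dtype=float)
    hist, _ = np.histogram(vec.to_numpy(), bins=edges)
    table = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_features": hist}
    )
    frac_ge_50 = float((vec >= 50).mean())
    return table, frac_ge_50


def category_fractions(matrix: CountMatrix) -> pd.Series:
    """Share of total read counts per feature class; sums to 1 over counted reads."""
    totals = matrix.counts.sum(axis=1).groupby(matrix.classes).sum()
    grand = totals.sum()
    if grand == 0:
        return totals.astype(float)
    return totals / grand
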