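"""Genome coordinate model: ORFs, operons, sRNA tracks, and interoperonic regions.

Interoperonic regions (IORs) are the maximal stretches of genomic DNA not covered
by any operon span; they are the search space for novel small RNAs. Coordinates
are 0-based half-open throughout the package; GFF3 interchange converts to the
1-based inclusive convention at the boundary (see :mod:`srnome.io`).

IORs are strandless: the underlying sequencing protocol this pipeline targets is
not strand-specific, so strand assignment of an intergenic transcript cannot be
supported by the data alone.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "Operon",
    "GenomeAnnotation",
    "IOR",
    "derive_iors",
    "flank_windows",
    "merge_intervals",
]


@dataclass(frozen=True)
class Feature:
    """A located genome feature (ORF, known sRNA, predicted sRNA)."""

    feature_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class Operon:
    """An operon: an ordered run of co-transcribed ORFs with a covering span."""

    operon_id: str
    member_orf_ids: tuple[str, ...]
    start: int
    end: int
    strand: str = "+"


@dataclass
class GenomeAnnotation:
    """A single contig's annotation: the coordinate backbone of the pipeline.

    Invariants (checked by :meth:`validate`): every feature lies within
    ``[0, contig_length)``; each operon span equals the union extent of its
    member ORFs; ids are unique within each track.
    """

    contig_id: str
    contig_length: int
    sequence: str | None = None
    orfs: list[Feature] = field(default_factory=list)
    operons: list[Operon] = field(default_factory=list)
    known_srnas: list[Feature] = field(default_factory=list)
    predicted_srnas: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._orf_index = {f.feature_id: f for f in self.orfs}

    def orf(self, orf_id: str) -> Feature:
        return self._orf_index[orf_id]

    def validate(self) -> None:
        if self.contig_length <= 0:
            raise ValueError("contig_length must be positive")
        if self.sequence is not None and len(self.sequence) != self.contig_length:
            raise ValueError("sequence length does not match contig_length")
        for track_name in ("orfs", "known_srnas", "predicted_srnas"):
            track = getattr(self, track_name)
            seen: set[str] = set()
            for f in track:
                if f.feature_id in seen:
                    raise ValueError(f"duplicate id {f.feature_id} in {track_name}")
                seen.add(f.feature_id)
                if not (0 <= f.start < f.end <= self.contig_length):
                    raise ValueError(
                        f"{track_name} feature {f.feature_id} outside contig bounds"
                    )
        for op in self.operons:
            members = [self._orf_index[m] for m in op.member_orf_ids]
            if not members:
                raise ValueError(f"operon {op.operon_id} has no members")
            if op.start != min(m.start for m in members) or op.end != max(
                m.end for m in members
            ):
                raise ValueError(
                    f"operon {op.operon_id} span does not match member ORF extent"
                )


@dataclass(frozen=True)
class IOR:
    """An interoperonic region with its flanking ORF neighbors.

    Neighbor fields hold the ORF id immediately left (``end <= start``) and
    right (``start >= end``) of the region, if any.
    """

    ior_id: str
    start: int
    end: int
    left_neighbor: str | None = None
    left_strand: str | None = None
    right_neighbor: str | None = None
    right_strand: str | None = None

    def __len__(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly overlapping/adjacent intervals into disjoint sorted ones."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            if s < merged[-1][1]:
                log.warning("overlapping spans [%d,%d) and %s merged", s, e, merged[-1])
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def derive_iors(
    annotation: GenomeAnnotation, include_terminal: bool = True
) -> list[IOR]:
    """Compute interoperonic regions: the complement of operon spans on the contig.

    ORFs not assigned to any operon are treated as singleton operons before the
    complement is taken, so that all gene-covered DNA is excluded. Terminal
    segments (before the first / after the last span) are included only when
    ``include_terminal`` is set. Overlapping spans are merged with a warning.

    Returned IORs are disjoint, sorted by start, and numbered ``INTEROPnnnn``
    consecutively in genomic order; each carries its nearest left/right ORF
    neighbor.
    """
    n = annotation.contig_length
    in_operon = {m for op in annotation.operons for m in op.member_orf_ids}
    spans = [(op.start, op.end) for op in annotation.operons]
    spans += [
        (f.start, f.end) for f in annotation.orfs if f.feature_id not in in_operon
    ]
    merged = merge_intervals(spans)

    gaps: list[tuple[int, int]] = []
    if not merged:
        if include_terminal:
            gaps = [(0, n)]
    else:
        if include_terminal and merged[0][0] > 0:
            gaps.append((0, merged[0][0]))
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            if e1 < s2:
                gaps.append((e1, s2))
        if include_terminal and merged[-1][1] < n:
            gaps.append((merged[-1][1], n))

    orfs_sorted = sorted(annotation.orfs, key=lambda f: (f.start, f.end))
    starts = [f.start for f in orfs_sorted]
    ends = [f.end for f in orfs_sorted]

    iors: list[IOR] = []
    for i, (s, e) in enumerate(gaps, start=1):
        # ORFs are disjoint from gaps, so start/end order coincide and bisection
        # on either list finds the adjacent neighbor.
        li = bisect.bisect_right(ends, s) - 1
        ri = bisect.bisect_left(starts, e)
        left = orfs_sorted[li] if li >= 0 else None
        right = orfs_sorted[ri] if ri < len(orfs_sorted) else None
        iors.append(
            IOR(
                ior_id=f"INTEROP{i:04d}",
                start=s,
                end=e,
                left_neighbor=left.feature_id if left else None,
                left_strand=left.strand if left else None,
                right_neighbor=right.feature_id if right else None,
                right_strand=right.strand if right else None,
            )
        )
    return iors


def flank_windows(ior: IOR, w: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """The two ``w``-nt windows of an IOR adjacent to its left/right neighbors.

    For IORs shorter than ``2*w`` the windows overlap; at ``w >= len(ior)`` both
    saturate to the whole region.
    """
    if w < 1:
        raise ValueError("flank window width must be >= 1")
    width = min(w, len(ior))
    return (ior.start, ior.start + width), (ior.end - width, ior.end)
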