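"""Synthetic genome + multi-condition RNA-seq generator.

Emulates the study design the analysis assumes: a single low-GC (default 0.29)
contig with planted operons, planted small RNAs inside interoperonic regions
(a configurable fraction carrying an intrinsic-terminator + poly-U Hfq
cassette), UTR-bleed decoys abutting expressed ORFs, and a 7-condition x
4-time-point x R-replicate negative-binomial count design with multiplicative,
dose-monotone stress effects.

The generator is the ground-truth side of the pipeline's validation: the
emitted :class:`TruthTable` records each planted feature's class, baseline,
stress response and Hfq status, against which discovery precision/recall and
Hfq classification are scored.

Counts are negative binomial with variance ``mu + dispersion * mu**2`` around
``size_factor * scaled_baseline * effect``; counts are realized as uniformly
placed fixed-length read-start intervals within the feature. UTR-bleed decoys
are the one deliberate exception: their reads straddle the neighboring ORF
boundary so that the decoy's IOR-side coverage falls entirely inside the flank
window, reproducing the coverage shape of a transcript bleeding out of a gene
end (reads still extend at most ``read_length - 1`` nt beyond the window).
A small uniform Poisson background (default 0.5% of depth) is added so the
expression threshold is meaningfully exercised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Feature, GenomeAnnotation, Operon
from .motifs import HfqParams, TerminatorParams, classify_hfq, reverse_complement
from .quantify import ReadSet

log = logging.getLogger(__name__)

STRESSORS = ("butanol", "butyrate")
DOSES = ("low", "medium", "high")
DOSE_MM = {
    "butanol": {"low": 30.0, "medium": 60.0, "high": 90.0},
    "butyrate": {"low": 30.0, "medium": 40.0, "high": 50.0},
}
TIME_POINTS_MIN = (15, 30, 60, 75)
FOLD_BY_DOSE = {"low": 1.5, "medium": 2.0, "high": 4.0}
# Stress effects ramp in over the first sampling interval: at 15 min post
# stress the fold change is the square root of its plateau value.
TIME_RAMP_EXPONENT = {15: 0.5, 30: 1.0, 60: 1.0, 75: 1.0}


@dataclass(frozen=True)
class Library:
    library_id: str
    condition_id: str
    stressor: str  # "none", "butanol", "butyrate"
    dose: str  # "none", "low", "medium", "high"
    dose_mM: float
    time_min: int
    replicate: int


@dataclass
class StudyDesign:
    """The library layout: conditions x time points x replicates."""

    libraries: list[Library]
    read_length: int = 50

    def validate(self) -> None:
        control = {l.condition_id for l in self.libraries if l.stressor == "none"}
        if len(control) != 1:
            raise ValueError("design must have exactly one no-stress condition")
        reps = self.to_frame().groupby(["condition_id", "time_min"]).size()
        if reps.nunique() != 1:
            raise ValueError("every (condition, time) cell needs the same replicate count")

    @classmethod
    def default(cls, n_replicates: int = 2, read_length: int = 50) -> "StudyDesign":
        """Desk-scale replica of the full design: 7 conditions x 4 times x R reps."""
        libs: list[Library] = []
        conditions = [("none", "none")] + [
            (s, d) for s in STRESSORS for d in DOSES
        ]
        for stressor, dose in conditions:
            cond = "control" if stressor == "none" else f"{stressor}_{dose}"
            mm = 0.0 if stressor == "none" else DOSE_MM[stressor][dose]
            for t in TIME_POINTS_MIN:
                for r in range(1, n_replicates + 1):
                    libs.append(
                        Library(
                            library_id=f"{cond}_t{t}_r{r}",
                            condition_id=cond,
                            stressor=stressor,
                            dose=dose,
                            dose_mM=mm,
                            time_min=t,
                            replicate=r,
                        )
                    )
        design = cls(libraries=libs, read_length=read_length)
        design.validate()
        return design

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([l.__dict__ for l in self.libraries])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, read_length: int = 50) -> "StudyDesign":
        libs = [
            Library(
                library_id=str(r.library_id),
                condition_id=str(r.condition_id),
                stressor=str(r.stressor),
                dose=str(r.dose),
                dose_mM=float(r.dose_mM),
                time_min=int(r.time_min),
                replicate=int(r.replicate),
            )
            for r in df.itertuples()
        ]
        return cls(libraries=libs, read_length=read_length)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted feature."""

    feature_id: str
    klass: str  # orf | known_srna | structural | srna_true | utr_decoy
    start: int
    end: int
    strand: str
    baseline_mean: float
    direction: int  # +1 up, -1 down, 0 non-responsive
    responsive_to: tuple[str, ...]
    hfq_positive: bool
    has_terminator: bool
    decoy_side: str | None = None  # "left"/"right" for utr_decoy features

    def effect(self, stressor: str, dose: str, time_min: int) -> float:
        """Multiplicative expected-count effect; 1 for the no-stress condition."""
        if self.direction == 0 or stressor not in self.responsive_to or dose == "none":
            return 1.0
        fold = FOLD_BY_DOSE[dose] ** TIME_RAMP_EXPONENT[time_min]
        return fold if self.direction > 0 else 1.0 / fold


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def __post_init__(self) -> None:
        self._by_id = {r.feature_id: r for r in self.records}

    def __getitem__(self, feature_id: str) -> TruthRecord:
        return self._by_id[feature_id]

    def of_class(self, klass: str) -> list[TruthRecord]:
        return [r for r in self.records if r.klass == klass]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.records])
        df["responsive_to"] = df["responsive_to"].map(lambda t: ",".join(t))
        return df


class PackingError(RuntimeError):
    """Raised when the requested features cannot be placed on the contig."""


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


# Hfq cassette layout, spliced at the 3' end of positive sRNAs:
# [25 nt U/A-rich upstream] [8 nt GC stem] [4 nt loop] [8 nt stem'] [8 nt poly-U]
_CASSETTE_STEM5 = "GGCAGCCG"
_CASSETTE_LOOP = "TTCG"
_CASSETTE_TAIL = "T" * 8


def _hfq_cassette(rng: np.random.Generator) -> str:
    upstream = "".join(
        rng.choice(list("ACGT"), size=25, p=[0.30, 0.07, 0.08, 0.55])
    )
    return (
        upstream
        + _CASSETTE_STEM5
        + _CASSETTE_LOOP
        + reverse_complement(_CASSETTE_STEM5)
        + _CASSETTE_TAIL
    )


def simulate_genome(
    n_operons: int = 60,
    n_srnas: int = 20,
    n_decoys: int = 10,
    n_known_srnas: int = 8,
    n_structural: int = 2,
    n_spurious_predictions: int = 5,
    gc: float = 0.29,
    hfq_fraction: float = 0.5,
    responsive_fraction: float = 0.8,
    seed: int | None = None,
    contig_id: str = "chr",
    orfs_per_operon: tuple[int, int] = (1, 5),
    orf_length: tuple[int, int] = (300, 900),
    gap_length: tuple[int, int] = (500, 900),
    srna_length: tuple[int, int] = (48, 300),
    decoy_window: int = 50,
    flank_margin: int = 60,
) -> tuple[GenomeAnnotation, TruthTable]:
    """Build the planted genome and its ground truth.

    The contig is laid out as alternating inter-operon gaps and operons of 1-5
    ORFs; sRNAs (length range spanning validated sizes, ~48-300 nt) are planted
    centrally inside distinct gaps with at least ``flank_margin`` nt clearance
    from both gap ends, decoys occupy one flank window of a gap abutting an
    expressed ORF, and a computational-prediction track (the comparative-
    genomics stand-in) covers true/known sRNAs and decoys with small coordinate
    jitter, plus a few spurious calls in unused gaps.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the generator")
    if not 0 < gc < 1:
        raise ValueError("gc must be a fraction in (0, 1)")
    rng = np.random.default_rng(seed)

    n_feature_gaps = n_srnas + n_known_srnas + n_decoys + n_spurious_predictions
    n_gaps = n_operons + 1
    if n_feature_gaps > n_gaps:
        raise PackingError(
            f"cannot place {n_feature_gaps} gap features in {n_gaps} gaps; "
            "first unplaceable feature: "
            + ("srna_true" if n_srnas > n_gaps else "later track")
        )

    # ---- lay out operons and gaps -------------------------------------------------
    orfs: list[Feature] = []
    operons: list[Operon] = []
    gaps: list[tuple[int, int]] = []
    pos = 0
    orf_counter = 0
    structural_ids: list[str] = []
    structural_slots = set(
        rng.choice(n_operons, size=min(n_structural, n_operons), replace=False)
    )
    for k in range(n_operons):
        gap = int(rng.integers(gap_length[0], gap_length[1] + 1))
        gaps.append((pos, pos + gap))
        pos += gap
        strand = "+" if rng.random() < 0.5 else "-"
        if k in structural_slots:
            # structural RNA gene (tmRNA/6S analogue): a highly expressed
            # singleton operon
            orf_counter += 1
            fid = f"CAC{orf_counter:04d}"
            length = int(rng.integers(200, 400))
            orfs.append(Feature(fid, pos, pos + length, strand))
            operons.append(Operon(f"OP{k + 1:04d}", (fid,), pos, pos + length, strand))
            structural_ids.append(fid)
            pos += length
            continue
        n_orf = int(rng.integers(orfs_per_operon[0], orfs_per_operon[1] + 1))
        member_ids = []
        op_start = pos
        for j in range(n_orf):
            if j > 0:
                pos += int(rng.integers(20, 51))  # intra-operon spacing
            orf_counter += 1
            fid = f"CAC{orf_counter:04d}"
            length = int(rng.integers(orf_length[0], orf_length[1] + 1))
            orfs.append(Feature(fid, pos, pos + length, strand))
            member_ids.append(fid)
            pos += length
        operons.append(Operon(f"OP{k + 1:04d}", tuple(member_ids), op_start, pos, strand))
    final_gap = int(rng.integers(gap_length[0], gap_length[1] + 1))
    gaps.append((pos, pos + final_gap))
    contig_length = pos + final_gap

    sequence = list(_random_sequence(rng, contig_length, gc))

    # ---- assign gap features ------------------------------------------------------
    interior = [i for i in range(1, n_gaps - 1)]  # decoys need ORFs on both sides
    rng.shuffle(interior)
    if len(interior) < n_feature_gaps:
        raise PackingError("not enough interior gaps for the requested features")
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        out = interior[cursor : cursor + n]
        cursor += n
        return out

    srna_gaps = take(n_srnas)
    known_gaps = take(n_known_srnas)
    decoy_gaps = take(n_decoys)
    spurious_gaps = take(n_spurious_predictions)

    records: list[TruthRecord] = []
    known_srnas: list[Feature] = []
    predicted: list[Feature] = []
    pred_counter = 0

    hfq_params = HfqParams()
    term_params = TerminatorParams()

    def place_srna(gap_idx: int, fid: str, klass: str, hfq_positive: bool) -> Feature:
        nonlocal sequence
        gs, ge = gaps[gap_idx]
        avail = ge - gs - 2 * flank_margin
        lo = max(srna_length[0], 80 if hfq_positive else srna_length[0])
        hi = min(srna_length[1], avail)
        if hi < lo:
            raise PackingError(f"gap {gap_idx} too short for sRNA {fid}")
        length = int(rng.integers(lo, hi + 1))
        start = gs + flank_margin + int(rng.integers(0, avail - length + 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        if hfq_positive:
            # Resample until the cassette is the classifier's selected 3'-half
            # terminator: flanking sequence can otherwise form an overlapping,
            # equally scoring stem whose tail is not the poly-U tract.
            for _ in range(100):
                cassette = _hfq_cassette(rng)
                sequence[end - len(cassette) : end] = list(cassette)
                seq = "".join(sequence[start:end])
                if classify_hfq(seq, fid, hfq_params, term_params).is_hfq_target:
                    break
                sequence[start:end] = list(_random_sequence(rng, length, gc))
            else:
                raise PackingError(f"could not plant a clean Hfq cassette for {fid}")
        else:
            # Reject chance Hfq signatures so the planted labels are separable
            # at the classifier's default thresholds.
            for _ in range(100):
                seq = "".join(sequence[start:end])
                if not classify_hfq(seq, fid, hfq_params, term_params).is_hfq_target:
                    break
                sequence[start:end] = list(_random_sequence(rng, length, gc))
            else:
                raise PackingError(f"could not desaturate Hfq signal for {fid}")
        return Feature(fid, start, end, strand)

    def stress_response() -> tuple[int, tuple[str, ...]]:
        if rng.random() >= responsive_fraction:
            return 0, ()
        direction = 1 if rng.random() < 0.5 else -1
        if rng.random() < 0.4:
            return direction, STRESSORS
        return direction, (STRESSORS[int(rng.integers(0, 2))],)

    n_hfq = round(hfq_fraction * n_srnas)
    hfq_flags = [i < n_hfq for i in range(n_srnas)]
    for i, gap_idx in enumerate(srna_gaps):
        fid = f"SRNA{i + 1:04d}"
        feat = place_srna(gap_idx, fid, "srna_true", hfq_flags[i])
        direction, responsive = stress_response()
        records.append(
            TruthRecord(
                feature_id=fid,
                klass="srna_true",
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                baseline_mean=float(rng.uniform(200, 600)),
                direction=direction,
                responsive_to=responsive,
                hfq_positive=hfq_flags[i],
                has_terminator=hfq_flags[i],
            )
        )
        pred_counter += 1
        jit_s = int(rng.integers(0, 11))
        jit_e = int(rng.integers(0, 11))
        predicted.append(
            Feature(
                f"PRED{pred_counter:04d}",
                max(gaps[gap_idx][0], feat.start - jit_s),
                min(gaps[gap_idx][1], feat.end + jit_e),
                feat.strand,
            )
        )

    n_hfq_known = round(hfq_fraction * n_known_srnas)
    for i, gap_idx in enumerate(known_gaps):
        fid = f"KSRNA{i + 1:03d}"
        positive = i < n_hfq_known
        feat = place_srna(gap_idx, fid, "known_srna", positive)
        known_srnas.append(feat)
        direction, responsive = stress_response()
        records.append(
            TruthRecord(
                feature_id=fid,
                klass="known_srna",
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                baseline_mean=float(rng.uniform(200, 600)),
                direction=direction,
                responsive_to=responsive,
                hfq_positive=positive,
                has_terminator=positive,
            )
        )
        # the prediction track rediscovers known sRNAs too; these are excluded
        # from novel calling downstream via the known overlap
        pred_counter += 1
        predicted.append(
            Feature(f"PRED{pred_counter:04d}", feat.start, feat.end, feat.strand)
        )

    orf_by_id = {f.feature_id: f for f in orfs}
    orf_sorted = sorted(orfs, key=lambda f: f.start)
    decoy_neighbor_boost: list[str] = []
    for i, gap_idx in enumerate(decoy_gaps):
        gs, ge = gaps[gap_idx]
        side = "left" if rng.random() < 0.5 else "right"
        if side == "left":
            start, end = gs, gs + decoy_window
            neighbor = max(
                (f for f in orf_sorted if f.end <= gs), key=lambda f: f.end
            )
        else:
            start, end = ge - decoy_window, ge
            neighbor = min(
                (f for f in orf_sorted if f.start >= ge), key=lambda f: f.start
            )
        fid = f"DECOY{i + 1:03d}"
        records.append(
            TruthRecord(
                feature_id=fid,
                klass="utr_decoy",
                start=start,
                end=end,
                strand=neighbor.strand,
                baseline_mean=float(rng.uniform(200, 400)),
                direction=0,
                responsive_to=(),
                hfq_positive=False,
                has_terminator=False,
                decoy_side=side,
            )
        )
        decoy_neighbor_boost.append(neighbor.feature_id)
        pred_counter += 1
        predicted.append(
            Feature(
                f"PRED{pred_counter:04d}",
                start + int(rng.integers(0, 6)),
                end - int(rng.integers(0, 6)),
                ".",
            )
        )

    for gap_idx in spurious_gaps:
        gs, ge = gaps[gap_idx]
        pred_counter += 1
        length = int(rng.integers(60, 150))
        start = gs + flank_margin
        predicted.append(Feature(f"PRED{pred_counter:04d}", start, start + length, "."))

    # ---- ORF baselines ------------------------------------------------------------
    boost = set(decoy_neighbor_boost)
    for f in orfs:
        if f.feature_id in structural_ids:
            base = float(rng.uniform(1500, 3000))
            klass = "structural"
        else:
            base = float(rng.lognormal(mean=np.log(250), sigma=0.8))
            if f.feature_id in boost:
                base = max(base, 250.0)
            klass = "orf"
        records.append(
            TruthRecord(
                feature_id=f.feature_id,
                klass=klass,
                start=f.start,
                end=f.end,
                strand=f.strand,
                baseline_mean=base,
                direction=0,
                responsive_to=(),
                hfq_positive=False,
                has_terminator=False,
            )
        )

    annotation = GenomeAnnotation(
        contig_id=contig_id,
        contig_length=contig_length,
        sequence="".join(sequence),
        orfs=orfs,
        operons=operons,
        known_srnas=known_srnas,
        predicted_srnas=predicted,
    )
    annotation.validate()
    return annotation, TruthTable(records=records)


def simulate_counts(
    design: StudyDesign,
    truth: TruthTable,
    annotation: GenomeAnnotation,
    dispersion: float = 0.05,
    depth: int = 50_000,
    noise_rate: float = 0.005,
    size_factor_sigma: float = 0.15,
    seed: int | None = None,
) -> dict[str, ReadSet]:
    """Draw per-library NB counts and realize them as read-start intervals.

    Feature baselines are rescaled so their sum matches ``depth``; each library
    gets a lognormal size factor around 1; each feature/library count is NB
    with mean ``s_l * mu_f * effect`` and variance ``mu + dispersion * mu^2``
    (Poisson at dispersion 0). Background noise reads are Poisson at
    ``noise_rate * depth``, uniform over the contig.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the generator")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    L = design.read_length
    n_contig = annotation.contig_length

    recs = truth.records
    baselines = np.array([r.baseline_mean for r in recs])
    scale = depth / baselines.sum() if depth > 0 and baselines.sum() > 0 else 0.0

    readsets: dict[str, ReadSet] = {}
    for lib in design.libraries:
        s_l = float(rng.lognormal(mean=0.0, sigma=size_factor_sigma))
        effects = np.array(
            [r.effect(lib.stressor, lib.dose, lib.time_min) for r in recs]
        )
        mu = scale * baselines * effects * s_l
        if dispersion == 0:
            counts = rng.poisson(mu)
        else:
            r_nb = 1.0 / dispersion
            p_nb = r_nb / (r_nb + np.where(mu > 0, mu, 1.0))
            counts = np.where(mu > 0, rng.negative_binomial(r_nb, p_nb), 0)
        starts_parts: list[np.ndarray] = []
        for r, k in zip(recs, counts):
            if k == 0:
                continue
            if r.klass == "utr_decoy":
                if r.decoy_side == "left":
                    # UTR bleed out of the left neighbor: read ends fall in the
                    # flank window, so IOR-side coverage stays inside it
                    ends = rng.integers(r.start + 1, r.end + 1, size=k)
                    starts_parts.append(ends - L)
                else:
                    starts_parts.append(rng.integers(r.start, r.end, size=k))
            else:
                lo = max(0, min(r.start, r.end - L))
                hi = max(r.start, r.end - L)
                starts_parts.append(rng.integers(lo, hi + 1, size=k))
        if depth > 0 and noise_rate > 0:
            n_noise = rng.poisson(noise_rate * depth)
            if n_noise:
                starts_parts.append(rng.integers(0, max(1, n_contig - L), size=n_noise))
        starts = (
            np.concatenate(starts_parts) if starts_parts else np.empty(0, dtype=np.int64)
        )
        readsets[lib.library_id] = ReadSet(
            library_id=lib.library_id,
            contig_id=annotation.contig_id,
            read_length=L,
            starts=starts,
        )
    return readsets


def truth_feature_frame(truth: TruthTable) -> pd.DataFrame:
    """Feature table (id/class/start/end) for counting planted features directly."""
    df = truth.to_frame()
    return df.rename(columns={"klass": "class"})[
        ["feature_id", "class", "start", "end"]
    ]
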