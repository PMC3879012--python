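"""Sequence-level characterization of sRNAs.

Three independent analyses live here:

* **Rho-independent (intrinsic) terminator detection** — enumeration of
  inverted-repeat stem-loops within a parameter box, scored by a pairing count
  (GC pairs weighted up, mismatches down) plus the length of the downstream
  poly-U tract. This is a deliberately transparent, thermodynamics-free score:
  every placement is enumerated, so the detector is exactly checkable against a
  brute-force oracle.

* **Hfq-target classification** — a rule-based model of the canonical Hfq
  binding signature on trans-acting sRNAs: an intrinsic terminator in the 3'
  half, a poly-U tail immediately downstream of the stem, and a U-rich or
  AU-rich tract upstream of the stem. Thresholds are this package's declared
  defaults, exposed in :class:`HfqParams`.

* **Promoter PSSM scanning** — log-odds position-specific scoring matrices for
  the two-box (sigma-factor style, e.g. sigma-A TTGACA/TATAAT) promoter model,
  scanned over all spacer lengths in a configured range.

DNA and RNA alphabets are treated as equivalent (T == U); output positions are
0-based offsets into the input sequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

_BASES = "ACGT"
_ENC = {c: i for i, c in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def _encode(seq: str) -> np.ndarray:
    s = seq.upper().replace("U", "T")
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    out = np.full(len(s), -1, dtype=np.int8)
    for c, i in _ENC.items():
        out[arr == ord(c)] = i
    if (out < 0).any():
        pos = int(np.argmax(out < 0))
        raise ValueError(f"invalid character {seq[pos]!r} at position {pos}")
    return out


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# Rho-independent terminators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TerminatorParams:
    stem_min: int = 6
    stem_max: int = 12
    loop_min: int = 3
    loop_max: int = 10
    max_mismatch: int = 1
    allow_wobble: bool = True
    tail_gap: int = 3  # U run may start up to this many nt after the stem
    tail_window: int = 10  # window used by the Hfq tail criterion
    min_score: float = 8.0


@dataclass(frozen=True)
class TerminatorHit:
    """One stem-loop placement: 5' arm, loop, 3' arm, and its 3' U tract."""

    stem5_start: int
    stem5_end: int
    loop_start: int
    loop_end: int
    stem3_start: int
    stem3_end: int
    paired_bases: int
    wobble_pairs: int
    mismatches: int
    gc_pairs: int
    u_tail_len: int
    score: float


def _u_run_length(enc: np.ndarray, pos: int) -> int:
    n = 0
    t = _ENC["T"]
    while pos + n < len(enc) and enc[pos + n] == t:
        n += 1
    return n


def _tail_u_len(enc: np.ndarray, stem3_end: int, tail_gap: int) -> int:
    best = 0
    for p in range(stem3_end, min(stem3_end + tail_gap + 1, len(enc))):
        best = max(best, _u_run_length(enc, p))
    return best


def find_terminators(
    seq: str, params: TerminatorParams = TerminatorParams()
) -> list[TerminatorHit]:
    """Enumerate stem-loop placements and return scored, non-overlapping hits.

    Every (start, stem length, loop length) placement inside the parameter box
    is evaluated. A placement is a candidate when its mismatch count is within
    ``max_mismatch`` (G:U wobbles count as mismatches when ``allow_wobble`` is
    off) and its score reaches ``min_score``, with

    ``score = paired_bases + 0.5 * gc_pairs - mismatches + min(u_tail_len, 8)``.

    Candidates are ranked by score (ties: leftmost, then shorter stem, then
    shorter loop) and greedily accepted if their stem-loop extent does not
    overlap an already accepted hit, so nested sub-stems of one hairpin are
    reported once.
    """
    enc = _encode(seq)
    n = len(enc)
    if n < 2 * params.stem_min + params.loop_min:
        raise ValueError("sequence shorter than the minimal stem-loop")
    t, a, g, c = _ENC["T"], _ENC["A"], _ENC["G"], _ENC["C"]

    candidates: list[TerminatorHit] = []
    for s in range(params.stem_min, params.stem_max + 1):
        for l in range(params.loop_min, params.loop_max + 1):
            span = 2 * s + l
            n_pos = n - span + 1
            if n_pos <= 0:
                continue
            i = np.arange(n_pos)
            wc = np.zeros(n_pos, dtype=np.int32)
            wob = np.zeros(n_pos, dtype=np.int32)
            gc = np.zeros(n_pos, dtype=np.int32)
            for j in range(s):
                x = enc[i + j]
                y = enc[i + 2 * s + l - 1 - j]
                is_wc = ((x == a) & (y == t)) | ((x == t) & (y == a)) | (
                    (x == g) & (y == c)
                ) | ((x == c) & (y == g))
                is_wob = ((x == g) & (y == t)) | ((x == t) & (y == g))
                wc += is_wc
                wob += is_wob
                gc += ((x == g) & (y == c)) | ((x == c) & (y == g))
            if params.allow_wobble:
                mm = s - wc - wob
            else:
                mm = s - wc
                wob = np.zeros_like(wob)
            ok = mm <= params.max_mismatch
            for start in np.flatnonzero(ok):
                start = int(start)
                stem3_end = start + span
                u_tail = _tail_u_len(enc, stem3_end, params.tail_gap)
                score = (
                    float(wc[start])
                    + 0.5 * float(gc[start])
                    - float(mm[start])
                    + min(u_tail, 8)
                )
                if score < params.min_score:
                    continue
                candidates.append(
                    TerminatorHit(
                        stem5_start=start,
                        stem5_end=start + s,
                        loop_start=start + s,
                        loop_end=start + s + l,
                        stem3_start=start + s + l,
                        stem3_end=stem3_end,
                        paired_bases=int(wc[start]),
                        wobble_pairs=int(wob[start]),
                        mismatches=int(mm[start]),
                        gc_pairs=int(gc[start]),
                        u_tail_len=int(u_tail),
                        score=score,
                    )
                )

    candidates.sort(
        key=lambda h: (
            -h.score,
            h.stem5_start,
            h.stem5_end - h.stem5_start,
            h.loop_end - h.loop_start,
        )
    )
    accepted: list[TerminatorHit] = []
    for hit in candidates:
        if all(
            hit.stem3_end <= kept.stem5_start or kept.stem3_end <= hit.stem5_start
            for kept in accepted
        ):
            accepted.append(hit)
    return accepted


# --------------------------------------------------------------------------
# Hfq-target classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HfqParams:
    tail_min_u: int = 5
    tail_window: int = 10
    up_window: int = 25
    u_rich_min: float = 0.40
    au_rich_min: float = 0.70


@dataclass(frozen=True)
class HfqCall:
    srna_id: str
    terminator: TerminatorHit | None
    tail_u_count_in_window: int
    upstream_u_fraction: float
    upstream_au_fraction: float
    has_terminator_3prime: bool
    has_poly_u_tail: bool
    has_u_rich_upstream: bool
    is_hfq_target: bool
    low_confidence: bool


def classify_hfq(
    srna_seq: str,
    srna_id: str = "",
    params: HfqParams = HfqParams(),
    term_params: TerminatorParams = TerminatorParams(),
) -> HfqCall:
    """Rule-based Hfq-target call on a full sRNA sequence (5'->3').

    Positive iff (a) an intrinsic terminator sits in the 3' half of the sRNA,
    (b) at least ``tail_min_u`` U's occur within ``tail_window`` nt downstream
    of the stem, and (c) the ``up_window`` nt upstream of the stem are U-rich
    (U fraction >= ``u_rich_min``) or AU-rich (A+U fraction >= ``au_rich_min``).
    Windows truncated by the sequence ends are evaluated as-is and flagged
    ``low_confidence``.
    """
    enc = _encode(srna_seq)
    n = len(enc)
    hits = []
    if n >= 2 * term_params.stem_min + term_params.loop_min:
        hits = [
            h
            for h in find_terminators(srna_seq, term_params)
            if (h.stem5_start + h.stem3_end) >= n  # stem-loop midpoint in 3' half
        ]
    term = max(hits, key=lambda h: h.score, default=None)

    t, a = _ENC["T"], _ENC["A"]
    low_confidence = False
    if term is None:
        tail_u = 0
        up_u_frac = up_au_frac = 0.0
        crit_tail = crit_up = False
    else:
        tail = enc[term.stem3_end : term.stem3_end + params.tail_window]
        if len(tail) < params.tail_window:
            low_confidence = True
        tail_u = int((tail == t).sum())
        crit_tail = tail_u >= params.tail_min_u
        up = enc[max(0, term.stem5_start - params.up_window) : term.stem5_start]
        if len(up) < params.up_window:
            low_confidence = True
        if len(up) == 0:
            up_u_frac = up_au_frac = 0.0
        else:
            up_u_frac = float((up == t).mean())
            up_au_frac = float(((up == t) | (up == a)).mean())
        crit_up = up_u_frac >= params.u_rich_min or up_au_frac >= params.au_rich_min

    return HfqCall(
        srna_id=srna_id,
        terminator=term,
        tail_u_count_in_window=tail_u,
        upstream_u_fraction=up_u_frac,
        upstream_au_fraction=up_au_frac,
        has_terminator_3prime=term is not None,
        has_poly_u_tail=crit_tail,
        has_u_rich_upstream=crit_up,
        is_hfq_target=term is not None and crit_tail and crit_up,
        low_confidence=low_confidence,
    )


# --------------------------------------------------------------------------
# Promoter PSSMs
# --------------------------------------------------------------------------

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass
class PSSM:
    """Per-position log2-odds over ACGT with a declared background."""

    matrix: np.ndarray  # shape (width, 4)
    background: tuple[float, float, float, float]
    name: str = "pssm"

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def score(self, seq: str, pos: int = 0) -> float:
        enc = _encode(seq[pos : pos + self.width])
        if len(enc) < self.width:
            raise ValueError("sequence shorter than PSSM width")
        return float(self.matrix[np.arange(self.width), enc].sum())

    def scores(self, enc: np.ndarray) -> np.ndarray:
        """Score every placement of the matrix along an encoded sequence."""
        n = len(enc) - self.width + 1
        if n <= 0:
            return np.empty(0)
        out = np.zeros(n)
        for j in range(self.width):
            out += self.matrix[j, enc[j : j + n]]
        return out


def build_pssm(
    aligned_sites: list[str],
    pseudocount: float = 0.5,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
    name: str = "pssm",
) -> PSSM:
    """Log-odds matrix from equal-length aligned sites with pseudocounts.

    Entry (j, b) is ``log2(((count_jb + pc) / (n + 4 pc)) / background_b)``.
    """
    if not aligned_sites:
        raise ValueError("need at least one site")
    width = len(aligned_sites[0])
    if any(len(s) != width for s in aligned_sites):
        raise ValueError("aligned sites must have equal lengths")
    counts = np.zeros((width, 4))
    for site in aligned_sites:
        enc = _encode(site)
        counts[np.arange(width), enc] += 1
    n = len(aligned_sites)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("background must sum to 1")
    return PSSM(matrix=np.log2(probs / bg), background=tuple(bg), name=name)


def write_pssm(path, pssm: PSSM, counts: np.ndarray | None = None) -> None:
    """JASPAR-like text: background header line, then one row per base."""
    mat = pssm.matrix
    lines = [f">{pssm.name} background={','.join(f'{b:g}' for b in pssm.background)}"]
    for i, base in enumerate(_BASES):
        vals = " ".join(f"{v:.6f}" for v in mat[:, i])
        lines.append(f"{base} [ {vals} ]")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pssm(path) -> PSSM:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    header = lines[0]
    name = header[1:].split()[0]
    bg = tuple(float(x) for x in header.split("background=")[1].split(","))
    rows = {}
    for ln in lines[1:]:
        base, rest = ln.split("[")
        rows[base.strip()] = [float(x) for x in rest.rstrip("]").split()]
    mat = np.array([rows[b] for b in _BASES]).T
    return PSSM(matrix=mat, background=bg, name=name)


@dataclass(frozen=True)
class PromoterHit:
    minus35_pos: int
    minus10_pos: int
    spacer_len: int
    score35: float
    score10: float
    combined_score: float


def scan_promoter(
    seq: str,
    pssm35: PSSM,
    pssm10: PSSM,
    spacer_min: int = 15,
    spacer_max: int = 19,
    score_min: float | None = None,
) -> list[PromoterHit]:
    """All two-box placements with spacer in range, sorted by combined score.

    Ties are broken by leftmost -35 position, then shortest spacer. When
    ``score_min`` is given only hits with ``combined_score >= score_min`` are
    returned.
    """
    enc = _encode(seq)
    min_len = pssm35.width + spacer_min + pssm10.width
    if len(enc) < min_len:
        raise ValueError("sequence shorter than minimal promoter placement")
    s35 = pssm35.scores(enc)
    s10 = pssm10.scores(enc)
    hits: list[PromoterHit] = []
    for spacer in range(spacer_min, spacer_max + 1):
        offset = pssm35.width + spacer
        n = len(enc) - offset - pssm10.width + 1
        if n <= 0:
            continue
        combined = s35[:n] + s10[offset : offset + n]
        for p in range(n):
            score = float(combined[p])
            if score_min is not None and score < score_min:
                continue
            hits.append(
                PromoterHit(
                    minus35_pos=p,
                    minus10_pos=p + offset,
                    spacer_len=spacer,
                    score35=float(s35[p]),
                    score10=float(s10[p + offset]),
                    combined_score=score,
                )
            )
    hits.sort(key=lambda h: (-h.combined_score, h.minus35_pos, h.spacer_len))
    return hits


SIGMA_A_MINUS35 = "TTGACA"
SIGMA_A_MINUS10 = "TATAAT"


def sigma_a_pssms(pseudocount: float = 0.5) -> tuple[PSSM, PSSM]:
    """Worked-example PSSM pair for the housekeeping sigma factor consensus."""
    return (
        build_pssm([SIGMA_A_MINUS35], pseudocount, name="sigmaA_minus35"),
        build_pssm([SIGMA_A_MINUS10], pseudocount, name="sigmaA_minus10"),
    )
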