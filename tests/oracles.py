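"""Independent brute-force reference implementations used only by the tests.

Each oracle re-derives the quantity from its definition by direct enumeration
(per-base scans, all-pairs overlap checks, exhaustive placements), staying
deliberately independent of the library's vectorized code paths.
"""

from __future__ import annotations

import numpy as np

COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def brute_ior_complement(contig_length, spans, include_terminal):
    """Per-base membership scan: bases covered by no span, grouped into runs."""
    covered = np.zeros(contig_length, dtype=bool)
    for s, e in spans:
        covered[s:e] = True
    gaps = []
    i = 0
    while i < contig_length:
        if not covered[i]:
            j = i
            while j < contig_length and not covered[j]:
                j += 1
            gaps.append((i, j))
            i = j
        else:
            i += 1
    if not include_terminal:
        n_spans_before = lambda pos: any(s < pos for s, _ in spans)
        n_spans_after = lambda pos: any(e > pos for _, e in spans)
        gaps = [(s, e) for s, e in gaps if n_spans_before(s) and n_spans_after(e)]
    return gaps


def brute_count_reads(read_starts, read_length, features, min_overlap_frac):
    """All-pairs overlap check against the fractional-overlap counting rule."""
    import math

    m = math.ceil(min_overlap_frac * read_length)
    out = {}
    for fid, fs, fe in features:
        n = 0
        for r in read_starts:
            overlap = min(fe, r + read_length) - max(fs, r)
            if overlap >= m:
                n += 1
        out[fid] = n
    return out


def brute_coverage(read_starts, read_length, ior_start, ior_end):
    """Per-base membership count."""
    cov = np.zeros(ior_end - ior_start, dtype=int)
    for r in read_starts:
        for pos in range(max(r, ior_start), min(r + read_length, ior_end)):
            cov[pos - ior_start] += 1
    return cov


def brute_percentile_ranks(values):
    """Sort-based percentile with mean-of-positions tie handling."""
    values = list(values)
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    pos_pct = [100.0 * r / (n - 1) for r in range(n)]
    out = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and values[order[j]] == values[order[i]]:
            j += 1
        mean_pct = sum(pos_pct[i:j]) / (j - i)
        for k in range(i, j):
            out[order[k]] = mean_pct
        i = j
    return out


def brute_find_terminators(seq, params):
    """Exhaustive (start, stem, loop) placement scan with the same scoring rule,
    written independently as nested loops over characters."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    cands = []
    for s in range(params.stem_min, params.stem_max + 1):
        for l in range(params.loop_min, params.loop_max + 1):
            for i in range(0, n - (2 * s + l) + 1):
                stem5 = seq[i : i + s]
                stem3 = seq[i + s + l : i + 2 * s + l]
                wc = wob = gc = 0
                for j in range(s):
                    x, y = stem5[j], stem3[s - 1 - j]
                    if COMP[x] == y:
                        wc += 1
                        if x in "GC":
                            gc += 1
                    elif {x, y} == {"G", "T"}:
                        wob += 1
                if params.allow_wobble:
                    mm = s - wc - wob
                else:
                    mm = s - wc
                    wob = 0
                if mm > params.max_mismatch:
                    continue
                stem3_end = i + 2 * s + l
                u_tail = 0
                for p in range(stem3_end, min(stem3_end + params.tail_gap + 1, n)):
                    run = 0
                    while p + run < n and seq[p + run] == "T":
                        run += 1
                    u_tail = max(u_tail, run)
                score = wc + 0.5 * gc - mm + min(u_tail, 8)
                if score < params.min_score:
                    continue
                cands.append(
                    {
                        "stem5_start": i,
                        "stem3_end": stem3_end,
                        "stem": s,
                        "loop": l,
                        "wc": wc,
                        "wob": wob,
                        "mm": mm,
                        "gc": gc,
                        "u_tail": u_tail,
                        "score": score,
                    }
                )
    cands.sort(key=lambda c: (-c["score"], c["stem5_start"], c["stem"], c["loop"]))
    kept = []
    for c in cands:
        if all(
            c["stem3_end"] <= k["stem5_start"] or k["stem3_end"] <= c["stem5_start"]
            for k in kept
        ):
            kept.append(c)
    return kept


def brute_scan_promoter(seq, p35, p10, spacer_min, spacer_max):
    """Exhaustive two-box placement scoring by per-character lookup."""
    seq = seq.upper().replace("U", "T")
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for pos35 in range(len(seq)):
        for spacer in range(spacer_min, spacer_max + 1):
            pos10 = pos35 + p35.width + spacer
            if pos10 + p10.width > len(seq):
                continue
            s35 = sum(
                p35.matrix[j, idx[seq[pos35 + j]]] for j in range(p35.width)
            )
            s10 = sum(
                p10.matrix[j, idx[seq[pos10 + j]]] for j in range(p10.width)
            )
            hits.append((pos35, pos10, spacer, float(s35 + s10)))
    hits.sort(key=lambda h: (-h[3], h[0], h[2]))
    return hits
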