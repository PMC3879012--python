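"""Characterize sRNA sequences: terminators, Hfq signatures, promoters.

Scans every known + planted sRNA for intrinsic (Rho-independent) terminators,
applies the rule-based Hfq-target model (3'-half terminator + poly-U tail +
U/AU-rich upstream tract), scores upstream regions with the sigma-A two-box
PSSM, and verifies the Hfq calls against the planted truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, load_study  # noqa: E402

import pandas as pd  # noqa: E402

from srnome.motifs import (  # noqa: E402
    classify_hfq,
    find_terminators,
    scan_promoter,
    sigma_a_pssms,
)


def main() -> None:
    annotation, truth, design, readsets = load_study()
    seq = annotation.sequence
    p35, p10 = sigma_a_pssms()

    rows, term_rows, prom_rows = [], [], []
    correct = 0
    records = truth.of_class("srna_true") + truth.of_class("known_srna")
    for rec in records:
        sub = seq[rec.start : rec.end]
        call = classify_hfq(sub, rec.feature_id)
        correct += int(call.is_hfq_target == rec.hfq_positive)
        rows.append(
            {
                "srna_id": rec.feature_id,
                "length_nt": rec.end - rec.start,
                "is_hfq_target": call.is_hfq_target,
                "truth_hfq": rec.hfq_positive,
                "has_terminator_3prime": call.has_terminator_3prime,
                "has_poly_u_tail": call.has_poly_u_tail,
                "has_u_rich_upstream": call.has_u_rich_upstream,
            }
        )
        for h in find_terminators(sub):
            term_rows.append(
                {
                    "srna_id": rec.feature_id,
                    "stem5_start": h.stem5_start,
                    "stem3_end": h.stem3_end,
                    "paired_bases": h.paired_bases,
                    "u_tail_len": h.u_tail_len,
                    "score": h.score,
                }
            )
        upstream = seq[max(0, rec.start - 60) : rec.start]
        hits = scan_promoter(upstream, p35, p10)
        if hits:
            prom_rows.append(
                {
                    "srna_id": rec.feature_id,
                    "minus35_pos": hits[0].minus35_pos,
                    "spacer_len": hits[0].spacer_len,
                    "combined_score": round(hits[0].combined_score, 3),
                }
            )

    pd.DataFrame(rows).to_csv(RESULTS / "hfq_calls.tsv", sep="\t", index=False)
    pd.DataFrame(term_rows).to_csv(RESULTS / "terminators.tsv", sep="\t", index=False)
    pd.DataFrame(prom_rows).to_csv(RESULTS / "promoter_hits.tsv", sep="\t", index=False)

    n_pos = sum(r["is_hfq_target"] for r in rows)
    print(f"{len(rows)} sRNAs scanned: {n_pos} Hfq targets called, "
          f"{correct}/{len(rows)} agree with planted truth")
    print(f"{len(term_rows)} terminator hits, {len(prom_rows)} upstream promoter scores")


if __name__ == "__main__":
    main()
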