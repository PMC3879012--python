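"""Call novel sRNAs: threshold, prediction intersection, UTR filter, naming.

Runs the three-stage screen over interoperonic regions and scores the calls
against the planted truth. Writes the full candidate ledger (one row per IOR
with every intermediate quantity) and the surviving novel sRNAs as BED.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, count_study, load_study  # noqa: E402

import pandas as pd  # noqa: E402

from srnome import io as sio  # noqa: E402
from srnome.discover import STATUS_NOVEL, run_discovery  # noqa: E402
from srnome.quantify import summed_coverage  # noqa: E402


def main() -> None:
    annotation, truth, design, readsets = load_study()
    iors, matrix, readset_list = count_study(annotation, truth, design, readsets)
    coverage = {r.ior_id: summed_coverage(readset_list, r) for r in iors}
    ledger = run_discovery(matrix, coverage, iors, annotation)
    ledger.to_csv(RESULTS / "candidates.tsv", sep="\t", index=False)

    novel = ledger[ledger["status"] == STATUS_NOVEL]
    sio.write_bed(
        RESULTS / "novel_srnas.bed",
        pd.DataFrame(
            {
                "chrom": annotation.contig_id,
                "start": novel["start"],
                "end": novel["end"],
                "name": novel["assigned_name"],
                "score": 0,
                "strand": ".",
            }
        ),
    )

    by_status = ledger["status"].value_counts()
    print(f"{len(iors)} IORs -> {int(ledger['passed_threshold'].sum())} expressed "
          f"(count >= 50 in >= 1 library)")
    for status, n in by_status.items():
        print(f"  {status:24s} {n}")

    # score against the planted truth
    true_iors = {
        r.ior_id
        for rec in truth.of_class("srna_true")
        for r in iors
        if rec.start < r.end and r.start < rec.end
    }
    called = set(novel["ior_id"])
    tp = len(called & true_iors)
    print(f"precision {tp / len(called):.3f}, recall {tp / len(true_iors):.3f} "
          f"({tp}/{len(called)} called, {len(true_iors)} planted)")


if __name__ == "__main__":
    main()
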