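"""Pairwise NB differential expression of the sRNA set under graded stress.

Tests each (stressor, dose, time point) against the matched-time no-stress
control over the known + novel sRNA features, with median-of-ratios size
factors and a pooled method-of-moments dispersion. Writes per-contrast
results and the up/down summary per stress level, and checks direction
against the planted stress responses.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, count_study, load_study  # noqa: E402

from srnome.discover import STATUS_NOVEL, run_discovery  # noqa: E402
from srnome.quantify import summed_coverage  # noqa: E402
from srnome.stresscompare import call_de, de_summary  # noqa: E402


def main() -> None:
    annotation, truth, design, readsets = load_study()
    iors, matrix, readset_list = count_study(annotation, truth, design, readsets)
    coverage = {r.ior_id: summed_coverage(readset_list, r) for r in iors}
    ledger = run_discovery(matrix, coverage, iors, annotation)
    novel = ledger[ledger["status"] == STATUS_NOVEL]
    srna_features = list(matrix.counts.index[matrix.classes == "known_srna"])
    srna_features += list(novel["ior_id"])

    de = call_de(matrix, design, alpha=0.05, features=srna_features)
    de.to_csv(RESULTS / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
    summary = de_summary(de)
    summary.to_csv(RESULTS / "de_summary.tsv", sep="\t", index=False)

    print(f"{len(srna_features)} sRNA features x {de.groupby(['stressor','dose','time_min']).ngroups} contrasts")
    print(summary.to_string(index=False))

    # direction agreement with the planted responses
    name_to_ior = {}
    ior_bounds = {r.ior_id: (r.start, r.end) for r in iors}
    agree = total = 0
    for rec in truth.of_class("srna_true") + truth.of_class("known_srna"):
        if rec.direction == 0:
            continue
        fid = rec.feature_id
        if rec.klass == "srna_true":
            hits = [
                i for i, (s, e) in ior_bounds.items() if rec.start < e and s < rec.end
            ]
            if not hits or hits[0] not in set(srna_features):
                continue
            fid = hits[0]
        sub = de[(de.feature_id == fid) & de.significant]
        sub = sub[sub.stressor.isin(rec.responsive_to)]
        if sub.empty:
            continue
        total += 1
        want = "up" if rec.direction > 0 else "down"
        if (sub.direction == want).mean() > 0.5:
            agree += 1
    print(f"direction agreement with planted truth: {agree}/{total}")


if __name__ == "__main__":
    main()
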