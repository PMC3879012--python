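"""Cluster sRNA expression patterns and rank abundances.

Builds the log2 stress/control ratio matrix per (stressor, dose, time),
hierarchically clusters it (Pearson distance, average linkage, k=4) and
computes within-library abundance percentiles, mirroring the heat-map +
intensity-ranking view of stress-responsive sRNA behavior.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, count_study, load_study  # noqa: E402

from srnome.discover import STATUS_NOVEL, run_discovery  # noqa: E402
from srnome.quantify import summed_coverage  # noqa: E402
from srnome.stresscompare import (  # noqa: E402
    hcluster,
    percentile_rank,
    ratio_matrix,
    size_factors,
)


def main() -> None:
    annotation, truth, design, readsets = load_study()
    iors, matrix, readset_list = count_study(annotation, truth, design, readsets)
    coverage = {r.ior_id: summed_coverage(readset_list, r) for r in iors}
    ledger = run_discovery(matrix, coverage, iors, annotation)
    novel = ledger[ledger["status"] == STATUS_NOVEL]
    names = dict(zip(novel["ior_id"], novel["assigned_name"]))
    srna_features = list(matrix.counts.index[matrix.classes == "known_srna"]) + list(names)

    factors = size_factors(matrix.counts)
    ratios = ratio_matrix(matrix, design, factors, features=srna_features)
    ratios.index = [names.get(f, f) for f in ratios.index]
    ratios.to_csv(RESULTS / "ratio_matrix.tsv", sep="\t", float_format="%.4f")

    clust = hcluster(ratios, k=4)
    clust.labels.rename("cluster").to_csv(RESULTS / "clusters.tsv", sep="\t")
    (RESULTS / "cluster_tree.nwk").write_text(clust.newick + "\n")

    pct = percentile_rank(matrix.counts.loc[srna_features], factors)
    pct.index = [names.get(f, f) for f in pct.index]
    pct.to_csv(RESULTS / "percentile_ranks.tsv", sep="\t", float_format="%.2f")

    print(f"clustered {len(ratios)} sRNAs x {ratios.shape[1]} contrasts into "
          f"{clust.labels.nunique()} clusters")
    for c in sorted(clust.labels.unique()):
        members = clust.labels[clust.labels == c].index
        mean_ratio = ratios.loc[members].to_numpy().mean()
        print(f"  cluster {c}: {len(members):2d} sRNAs, mean log2 ratio {mean_ratio:+.2f}")


if __name__ == "__main__":
    main()
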