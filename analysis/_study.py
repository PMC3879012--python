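"""Shared settings for the numbered analysis scripts.

One seed drives the whole study; every script regenerates the synthetic data
deterministically from it (generation takes well under a second), so no bulky
intermediate read files need to be kept on disk. Tables land under results/.
"""

from pathlib import Path

SEED = 20260927
RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def load_study():
    """Deterministically rebuild the synthetic study (genome, truth, reads)."""
    from srnome.simulate import StudyDesign, simulate_counts, simulate_genome

    annotation, truth = simulate_genome(seed=SEED)
    design = StudyDesign.default(n_replicates=2)
    readsets = simulate_counts(design, truth, annotation, seed=SEED + 1)
    return annotation, truth, design, readsets


def count_study(annotation, truth, design, readsets):
    """Feature table + count matrix + IORs for the study."""
    import pandas as pd

    from srnome.annotation import derive_iors
    from srnome.quantify import build_count_matrix

    iors = derive_iors(annotation)
    structural = {r.feature_id for r in truth.of_class("structural")}
    rows = [
        (f.feature_id, "structural" if f.feature_id in structural else "orf", f.start, f.end)
        for f in annotation.orfs
    ]
    rows += [(f.feature_id, "known_srna", f.start, f.end) for f in annotation.known_srnas]
    rows += [(r.ior_id, "ior", r.start, r.end) for r in iors]
    features = pd.DataFrame(rows, columns=["feature_id", "class", "start", "end"])
    readset_list = [readsets[lib.library_id] for lib in design.libraries]
    matrix = build_count_matrix(readset_list, features, 0.5, annotation.contig_length)
    return iors, matrix, readset_list
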