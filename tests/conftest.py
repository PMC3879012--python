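import numpy as np
import pytest

from srnome.annotation import Feature, GenomeAnnotation, Operon
from srnome.pipeline import RunConfig, run_pipeline
from srnome.simulate import StudyDesign, simulate_counts, simulate_genome


@pytest.fixture(scope="session")
def small_annotation() -> GenomeAnnotation:
    """Tiny hand-built contig: two operons, one singleton ORF, one known sRNA."""
    orfs = [
        Feature("CAC0001", 100, 300, "+"),
        Feature("CAC0002", 320, 500, "+"),
        Feature("CAC0003", 700, 900, "-"),
        Feature("CAC0004", 1500, 1700, "+"),
    ]
    operons = [
        Operon("OP1", ("CAC0001", "CAC0002"), 100, 500, "+"),
        Operon("OP2", ("CAC0003",), 700, 900, "-"),
    ]
    ann = GenomeAnnotation(
        contig_id="chr",
        contig_length=2000,
        orfs=orfs,
        operons=operons,
        known_srnas=[Feature("KSRNA001", 1000, 1100, "+")],
        predicted_srnas=[Feature("PRED0001", 1020, 1080, "+")],
    )
    ann.validate()
    return ann


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-scale planted genome + counts; shared across tests (read-only)."""
    annotation, truth = simulate_genome(seed=123)
    design = StudyDesign.default(n_replicates=2)
    readsets = simulate_counts(design, truth, annotation, seed=124)
    return annotation, truth, design, readsets


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default pipeline run; reused by discovery/DE/motif checks."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(seed=202, outdir=str(out))
    report = run_pipeline(cfg)
    return cfg, report, out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
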