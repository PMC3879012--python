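"""End-to-end orchestration: simulate -> quantify -> discover -> compare -> motifs.

A single declarative :class:`RunConfig` drives the run; every stage default is
echoed into the run report so a run is self-documenting, and a manifest of
SHA-256 content hashes over all emitted tables makes determinism checkable:
identical config + seed gives identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .annotation import GenomeAnnotation, derive_iors
from .discover import STATUS_NOVEL, run_discovery
from .motifs import (
    HfqParams,
    TerminatorParams,
    classify_hfq,
    find_terminators,
    scan_promoter,
    sigma_a_pssms,
)
from .quantify import (
    CountMatrix,
    ReadSet,
    build_count_matrix,
    category_fractions,
    readcount_histogram,
    summed_coverage,
)
from .simulate import (
    StudyDesign,
    TruthTable,
    simulate_counts,
    simulate_genome,
)
from .stresscompare import (
    call_de,
    de_summary,
    hcluster,
    percentile_rank,
    ratio_matrix,
    size_factors,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run. Seed is mandatory in simulate mode."""

    seed: int | None = None
    mode: str = "simulate+analyze"  # or "analyze-only"
    outdir: str = "run_out"

    # simulate
    n_operons: int = 60
    n_srnas: int = 20
    n_decoys: int = 10
    n_known_srnas: int = 8
    gc: float = 0.29
    hfq_fraction: float = 0.5
    n_replicates: int = 2
    depth: int = 50_000
    dispersion_sim: float = 0.05
    noise_rate: float = 0.005
    read_length: int = 50
    write_reads: bool = False

    # quantify
    min_overlap_frac: float = 0.5

    # discover
    min_count: int = 50
    min_library_fraction: float | None = None
    flank_w: int = 50
    dominance: float = 0.8
    neighbor_min: int = 50

    # stresscompare
    alpha: float = 0.05
    pseudocount: float = 1.0
    cluster_distance: str = "correlation"
    cluster_linkage: str = "average"
    cluster_k: int = 4

    # motifs
    terminator: dict = field(default_factory=dict)
    hfq: dict = field(default_factory=dict)
    promoter_upstream: int = 60

    # analyze-only inputs
    annotation_gff: str | None = None
    genome_fasta: str | None = None
    counts_tsv: str | None = None
    reads_dir: str | None = None

    def validate(self) -> None:
        if self.mode not in ("simulate+analyze", "analyze-only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate+analyze" and self.seed is None:
            raise ValueError("seed is mandatory in simulate mode")
        if not 0 < self.min_overlap_frac <= 1:
            raise ValueError("min_overlap_frac must be in (0, 1]")
        if not 0 < self.dominance <= 1:
            raise ValueError("dominance must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        # validation happens at run time, after any CLI overrides are applied
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunReport:
    config: dict
    manifest: dict[str, str]
    summary: dict
    timings: dict[str, float]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label, float_format="%.6g")


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the configured stages and write all tables under ``outdir``."""
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    summary: dict = {}
    term_params = TerminatorParams(**config.terminator)
    hfq_params = HfqParams(**config.hfq)

    # ---- simulate -----------------------------------------------------------------
    t0 = time.perf_counter()
    truth: TruthTable | None = None
    if config.mode == "simulate+analyze":
        annotation, truth = simulate_genome(
            n_operons=config.n_operons,
            n_srnas=config.n_srnas,
            n_decoys=config.n_decoys,
            n_known_srnas=config.n_known_srnas,
            gc=config.gc,
            hfq_fraction=config.hfq_fraction,
            seed=config.seed,
        )
        design = StudyDesign.default(
            n_replicates=config.n_replicates, read_length=config.read_length
        )
        readsets_map = simulate_counts(
            design,
            truth,
            annotation,
            dispersion=config.dispersion_sim,
            depth=config.depth,
            noise_rate=config.noise_rate,
            seed=config.seed + 1,
        )
        sio.write_fasta(out / "genome.fasta", {annotation.contig_id: annotation.sequence})
        sio.write_annotation_gff3(out / "annotation.gff3", annotation)
        sio.write_bed(
            out / "predicted_srnas.bed",
            sio.features_to_bed(annotation.contig_id, annotation.predicted_srnas),
        )
        _write_tsv(design.to_frame(), out / "design.tsv")
        _write_tsv(truth.to_frame(), out / "truth.tsv")
        if config.write_reads:
            reads_dir = out / "reads"
            reads_dir.mkdir(exist_ok=True)
            for lib_id, rs in readsets_map.items():
                sio.write_bed(reads_dir / f"{lib_id}.bed", rs.to_bed())
    else:
        if not (config.annotation_gff and config.genome_fasta and config.reads_dir):
            raise ValueError(
                "analyze-only mode needs annotation_gff, genome_fasta and reads_dir"
            )
        seqs = sio.read_fasta(config.genome_fasta)
        contig_id, sequence = next(iter(seqs.items()))
        annotation = sio.read_annotation_gff3(
            config.annotation_gff, len(sequence), sequence
        )
        design = StudyDesign.from_frame(
            pd.read_csv(Path(config.reads_dir) / "design.tsv", sep="\t"),
            read_length=config.read_length,
        )
        readsets_map = {}
        for lib in design.libraries:
            bed = sio.read_bed(Path(config.reads_dir) / f"{lib.library_id}.bed")
            readsets_map[lib.library_id] = ReadSet.from_bed(
                lib.library_id, bed, config.read_length
            )
    timings["simulate"] = time.perf_counter() - t0

    # ---- quantify -----------------------------------------------------------------
    t0 = time.perf_counter()
    iors = derive_iors(annotation, include_terminal=True)
    sio.write_ior_table(out / "iors.tsv", iors)
    # structural RNA genes are singleton operons marked in truth when available
    structural_ids = set()
    if truth is not None:
        structural_ids = {r.feature_id for r in truth.of_class("structural")}
    feature_rows = []
    for f in annotation.orfs:
        klass = "structural" if f.feature_id in structural_ids else "orf"
        feature_rows.append((f.feature_id, klass, f.start, f.end))
    for f in annotation.known_srnas:
        feature_rows.append((f.feature_id, "known_srna", f.start, f.end))
    for r in iors:
        feature_rows.append((r.ior_id, "ior", r.start, r.end))
    features = pd.DataFrame(
        feature_rows, columns=["feature_id", "class", "start", "end"]
    )
    readsets = [readsets_map[lib.library_id] for lib in design.libraries]
    matrix = build_count_matrix(
        readsets, features, config.min_overlap_frac, annotation.contig_length
    )
    matrix.to_tsv(out / "counts.tsv")
    fractions = category_fractions(matrix)
    frac_df = fractions.rename("count_share").reset_index()
    frac_df.columns = ["class", "count_share"]
    _write_tsv(frac_df, out / "category_fractions.tsv")
    hist_rows = []
    for klass in ("orf", "known_srna", "ior"):
        table, frac = readcount_histogram(matrix, klass)
        table.insert(0, "class", klass)
        table["fraction_ge_50"] = frac
        hist_rows.append(table)
    _write_tsv(pd.concat(hist_rows, ignore_index=True), out / "readcount_histograms.tsv")
    timings["quantify"] = time.perf_counter() - t0

    # ---- discover -----------------------------------------------------------------
    t0 = time.perf_counter()
    coverage_by_ior = {r.ior_id: summed_coverage(readsets, r) for r in iors}
    ledger = run_discovery(
        matrix,
        coverage_by_ior,
        iors,
        annotation,
        min_count=config.min_count,
        min_library_fraction=config.min_library_fraction,
        flank_w=config.flank_w,
        dominance=config.dominance,
        neighbor_min=config.neighbor_min,
    )
    _write_tsv(ledger, out / "candidates.tsv")
    novel = ledger[ledger["status"] == STATUS_NOVEL]
    novel_bed = pd.DataFrame(
        {
            "chrom": annotation.contig_id,
            "start": novel["start"],
            "end": novel["end"],
            "name": novel["assigned_name"],
            "score": 0,
            "strand": ".",
        }
    )
    sio.write_bed(out / "novel_srnas.bed", novel_bed)
    summary["n_iors"] = len(iors)
    summary["n_expressed_iors"] = int(ledger["passed_threshold"].sum())
    summary["n_candidates"] = int(
        ((ledger["predictions"] != "") & ledger["passed_threshold"]).sum()
    )
    summary["n_fp_utr"] = int((ledger["status"] == "fp_utr").sum())
    summary["n_novel_srnas"] = len(novel)
    timings["discover"] = time.perf_counter() - t0

    # ---- stresscompare ------------------------------------------------------------
    t0 = time.perf_counter()
    factors = size_factors(matrix.counts)
    _write_tsv(
        factors.reset_index().rename(columns={"index": "library_id"}),
        out / "size_factors.tsv",
    )
    srna_features = list(matrix.counts.index[matrix.classes == "known_srna"])
    novel_by_ior = dict(zip(novel["ior_id"], novel["assigned_name"]))
    srna_features += list(novel_by_ior)
    de = call_de(
        matrix,
        design,
        alpha=config.alpha,
        features=srna_features,
        pseudocount=config.pseudocount,
    )
    if not de.empty:
        de["feature_id"] = de["feature_id"].map(lambda f: novel_by_ior.get(f, f))
    _write_tsv(de, out / "de_results.tsv")
    _write_tsv(de_summary(de), out / "de_summary.tsv")
    ratios = ratio_matrix(
        matrix, design, factors, config.pseudocount, features=srna_features
    )
    ratios.index = [novel_by_ior.get(f, f) for f in ratios.index]
    _write_tsv(ratios, out / "ratio_matrix.tsv", index=True, index_label="feature_id")
    if len(ratios) >= 2:
        clust = hcluster(
            ratios,
            distance=config.cluster_distance,
            linkage_method=config.cluster_linkage,
            k=config.cluster_k,
        )
        _write_tsv(
            clust.labels.reset_index().rename(columns={"index": "feature_id"}),
            out / "clusters.tsv",
        )
        (out / "cluster_tree.nwk").write_text(clust.newick + "\n")
        summary["n_clusters"] = int(clust.labels.nunique())
    pct = percentile_rank(matrix.counts.loc[srna_features], factors)
    pct.index = [novel_by_ior.get(f, f) for f in pct.index]
    _write_tsv(pct, out / "percentile_ranks.tsv", index=True, index_label="feature_id")
    summary["n_srna_features"] = len(srna_features)
    if not de.empty:
        summary["n_de_up"] = int(
            de.loc[de["direction"] == "up", "feature_id"].nunique()
        )
        summary["n_de_down"] = int(
            de.loc[de["direction"] == "down", "feature_id"].nunique()
        )
    timings["stresscompare"] = time.perf_counter() - t0

    # ---- motifs -------------------------------------------------------------------
    t0 = time.perf_counter()
    seq = annotation.sequence
    srna_intervals: dict[str, tuple[int, int]] = {}
    for f in annotation.known_srnas:
        srna_intervals[f.feature_id] = (f.start, f.end)
    pred_by_id = {p.feature_id: p for p in annotation.predicted_srnas}
    for ior_id, name in novel_by_ior.items():
        preds = ledger.loc[ledger["ior_id"] == ior_id, "predictions"].iloc[0].split(",")
        p = pred_by_id[preds[0]]
        srna_intervals[name] = (p.start, p.end)
    term_rows, hfq_rows, prom_rows = [], [], []
    if seq is not None:
        p35, p10 = sigma_a_pssms()
        for name, (s, e) in srna_intervals.items():
            sub = seq[s:e]
            for h in find_terminators(sub, term_params):
                term_rows.append({"srna_id": name, **asdict(h)})
            call = classify_hfq(sub, name, hfq_params, term_params)
            hfq_rows.append(
                {
                    "srna_id": name,
                    "is_hfq_target": call.is_hfq_target,
                    "has_terminator_3prime": call.has_terminator_3prime,
                    "has_poly_u_tail": call.has_poly_u_tail,
                    "has_u_rich_upstream": call.has_u_rich_upstream,
                    "tail_u_count": call.tail_u_count_in_window,
                    "upstream_u_fraction": round(call.upstream_u_fraction, 4),
                    "upstream_au_fraction": round(call.upstream_au_fraction, 4),
                    "low_confidence": call.low_confidence,
                }
            )
            up = seq[max(0, s - config.promoter_upstream) : s]
            if len(up) >= p35.width + 15 + p10.width:
                hits = scan_promoter(up, p35, p10, score_min=6.0)
                if hits:
                    best = hits[0]
                    prom_rows.append(
                        {
                            "srna_id": name,
                            "minus35_pos": best.minus35_pos,
                            "minus10_pos": best.minus10_pos,
                            "spacer_len": best.spacer_len,
                            "combined_score": round(best.combined_score, 4),
                        }
                    )
        _write_tsv(pd.DataFrame(term_rows), out / "terminators.tsv")
        _write_tsv(pd.DataFrame(hfq_rows), out / "hfq_calls.tsv")
        _write_tsv(pd.DataFrame(prom_rows), out / "promoter_hits.tsv")
        summary["n_hfq_targets"] = int(
            sum(r["is_hfq_target"] for r in hfq_rows)
        )
    timings["motifs"] = time.perf_counter() - t0

    # ---- truth-based evaluation ---------------------------------------------------
    if truth is not None:
        summary["evaluation"] = evaluate_against_truth(
            ledger, iors, truth, annotation, hfq_params, term_params
        )

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.glob("*"))
        if p.is_file() and p.name != "report.json"
    }
    report = RunReport(
        config=config.to_dict(), manifest=manifest, summary=summary, timings=timings
    )
    (out / "report.json").write_text(
        json.dumps(
            {
                "config": report.config,
                "summary": report.summary,
                "timings": {k: round(v, 3) for k, v in report.timings.items()},
                "manifest": report.manifest,
            },
            indent=2,
            default=str,
        )
    )
    return report


def evaluate_against_truth(
    ledger: pd.DataFrame,
    iors,
    truth: TruthTable,
    annotation: GenomeAnnotation,
    hfq_params: HfqParams,
    term_params: TerminatorParams,
) -> dict:
    """Precision/recall of novel calls and Hfq accuracy against planted truth."""
    true_iors = set()
    by_interval = [(r.start, r.end, r.ior_id) for r in iors]
    for rec in truth.of_class("srna_true"):
        for s, e, ior_id in by_interval:
            if rec.start < e and s < rec.end:
                true_iors.add(ior_id)
                break
    called = set(ledger.loc[ledger["status"] == STATUS_NOVEL, "ior_id"])
    tp = len(called & true_iors)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(true_iors) if true_iors else float("nan")

    decoy_iors = set()
    for rec in truth.of_class("utr_decoy"):
        for s, e, ior_id in by_interval:
            if rec.start < e and s < rec.end:
                decoy_iors.add(ior_id)
                break
    decoy_rows = ledger[ledger["ior_id"].isin(decoy_iors)]
    decoys_eliminated = int((decoy_rows["status"] == "fp_utr").sum())

    hfq_correct = 0
    hfq_total = 0
    seq = annotation.sequence
    if seq is not None:
        for rec in truth.of_class("srna_true") + truth.of_class("known_srna"):
            call = classify_hfq(
                seq[rec.start : rec.end], rec.feature_id, hfq_params, term_params
            )
            hfq_total += 1
            hfq_correct += int(call.is_hfq_target == rec.hfq_positive)
    return {
        "novel_true_positive": tp,
        "novel_called": len(called),
        "novel_truth": len(true_iors),
        "precision": precision,
        "recall": recall,
        "n_decoy_iors": len(decoy_iors),
        "decoys_eliminated": decoys_eliminated,
        "hfq_correct": hfq_correct,
        "hfq_total": hfq_total,
        "hfq_accuracy": hfq_correct / hfq_total if hfq_total else float("nan"),
    }
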