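# srnome

Genome-scale discovery and characterization of stress-responsive bacterial
small RNAs (sRNAs) from RNA-seq, built around the workflow used to map the
small RNome of *Clostridium acetobutylicum* under butanol and butyrate
stress. The package is for computational biologists who want a reproducible,
fully testable implementation of that style of analysis: every stage that was
originally manual, external, or database-driven is an explicit, parameterized
rule.

## What it computes

Given a genome annotation (ORFs + operons), mapped reads as intervals, a
computational sRNA-prediction track, and a study design table, the pipeline:

1. **Derives interoperonic regions (IORs)** — maximal intervals not covered
   by any operon span (unassigned ORFs count as singleton operons); the
   search space for novel sRNAs.
2. **Counts reads** per feature (read counts ≥ 50% read-length overlap,
   unstranded) and builds per-base IOR coverage.
3. **Calls candidates**: an IOR is *expressed* when its raw count reaches
   `min_count = 50` in at least one library; expressed IORs must contain a
   computational sRNA prediction; candidates whose coverage sits
   predominantly (share ≥ 0.8) in the 50-nt flank windows abutting an
   *expressed* (count ≥ 50) neighboring ORF are eliminated as UTR bleed.
   Survivors are named `sCAC<n>` after the downstream ORF locus.
4. **Tests differential expression** per (stressor, dose, time point) against
   the matched-time no-stress control: median-of-ratios size factors
   `ŝ_l = median_f (k_fl / (∏_j k_fj)^(1/m))`, negative-binomial model with
   variance `μ + αμ²`, and an exact conditional two-group test on the group
   sums (normal approximation for totals > 10⁴), thresholded at raw
   `p ≤ 0.05`.
5. **Clusters expression patterns**: log2 ratio matrices of normalized
   stress/control means, hierarchical clustering (Pearson distance, average
   linkage), and within-library abundance percentiles (0–100).
6. **Characterizes sequences**: intrinsic (Rho-independent) terminator
   detection by exhaustive stem-loop enumeration with a pairing + poly-U
   score; a rule-based Hfq-target model (3'-half terminator, ≥ 5 U within
   10 nt downstream of the stem, U-rich ≥ 0.40 or AU-rich ≥ 0.70 upstream
   tract); and σ^A two-box promoter scanning with log-odds PSSMs
   (TTGACA … 15–19 nt spacer … TATAAT).

A synthetic-data module generates the whole study — a low-GC (0.29) genome
with planted operons, sRNAs (some carrying the terminator + poly-U Hfq
cassette), UTR-bleed decoys, and NB counts with dose-monotone stress effects
— so every stage can be validated against planted ground truth. See
`docs/methods.md` for models, parameters and limitations.

## Worked example

```bash
srnome run-all --seed 11 --outdir run_out
```

runs the default scaled study (7 conditions × 4 time points × 2 replicates,
50 k reads/library, 20 planted sRNAs, 10 decoys) and prints:

```json
{
  "n_iors": 61,
  "n_expressed_iors": 38,
  "n_candidates": 30,
  "n_fp_utr": 10,
  "n_novel_srnas": 20,
  "n_clusters": 4,
  "n_srna_features": 28,
  "n_de_up": 16,
  "n_de_down": 16,
  "n_hfq_targets": 14,
  "evaluation": {
    "novel_true_positive": 20,
    "novel_called": 20,
    "novel_truth": 20,
    "precision": 1.0,
    "recall": 1.0,
    "n_decoy_iors": 10,
    "decoys_eliminated": 10,
    "hfq_correct": 28,
    "hfq_total": 28,
    "hfq_accuracy": 1.0
  }
}
```

Reading: of 61 IORs, 38 pass the count-50 threshold; 30 of those contain a
prediction; the UTR filter removes the 10 planted decoys and all 20 planted
sRNAs survive and are named (precision = recall = 1.0). The 28-member sRNA
set (8 known + 20 novel) is tested across 24 stress contrasts; 16 sRNAs come
up significantly up- and 16 down-regulated somewhere in the grid, and the
Hfq model reproduces all 28 planted labels. Output tables (candidate ledger,
DE results, ratio matrix, clusters, percentiles, terminator/Hfq/promoter
calls) and a SHA-256 manifest land in `run_out/`.

The same workflow is laid out as a narrated sequence under `analysis/`
(`01_simulate_study.py` … `06_sequence_characterization.py`), writing its
tables to `results/`.

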