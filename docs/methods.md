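# Methods

This note records the models, parameter choices and known limitations of the
pipeline. It is written for a reader who wants to judge what the package's
validation does and does not demonstrate.

## Coordinate model and IOR derivation

All coordinates are 0-based half-open internally; GFF3 output converts to
1-based inclusive. Interoperonic regions (IORs) are the maximal complement
intervals of the merged operon spans on a contig. Two policy decisions:

* **ORFs not assigned to an operon are treated as singleton operons** before
  the complement is taken, so IORs never overlap gene-covered DNA.
* **Terminal contig segments** (before the first and after the last span)
  are included as IORs by default (`include_terminal=True`); the inventory of
  a real genome is ambiguous on this point, so both readings are supported.

IORs are strandless throughout: the sequencing protocol this pipeline models
is not strand-specific, so strand assignment of an intergenic transcript is
not supported by the data. Overlapping operon annotations are merged with a
logged warning rather than rejected.

## Read counting

Reads are fixed-length start intervals. A read increments a feature iff
their overlap is at least `ceil(min_overlap_frac × read_length)` bases
(default fraction 0.5). The rule is symmetric and makes double counting
impossible for disjoint features at fractions above one half; a read
overlapping two *overlapping* features by ≥ half its length counts for both,
which is the correct unstranded behavior. Counts used for expression
thresholding are raw, un-normalized per-library sums — the threshold is a
detection limit, not a relative-abundance statement; normalized counts enter
only in differential expression and ratio matrices.

## Candidate calling

* **Expression threshold**: count ≥ `min_count` (default 50) in a quorum of
  libraries. The quorum defaults to a single library — the permissive reading
  that retains condition-specific sRNAs — and is exposed as
  `min_library_fraction` because a stricter quorum (e.g. 20% of libraries) is
  a defensible alternative for noisier data.
* **Prediction intersection** uses ≥ 1 nt overlap between an expressed IOR
  and a computational prediction track (supplied as BED; the pipeline never
  runs comparative genomics itself). Predictions that overlap already-known
  sRNAs are excluded from novel calling.
* **UTR false-positive filter**: the original screen was visual curation;
  here it is an explicit rule. A candidate is eliminated iff the coverage
  share of the two `w = 50` nt flank windows (union, not double-counting
  overlap for short IORs) is ≥ `dominance = 0.8` **and** the neighbor ORF on
  the dominant side has count ≥ 50 — bleed from an unexpressed gene is not
  credible, so such candidates are retained. IORs no longer than `w` cannot
  be tested (the window is the whole region); they are retained and flagged
  `needs_review`. Both thresholds are configuration values, declared as this
  package's defaults.
* **Naming**: survivors are named `sCAC<n>` from the numeric locus of the
  right-neighbor (downstream in genome order) ORF, falling back to the left
  neighbor at a contig end; survivors sharing a reference ORF get `a`, `b`, …
  suffixes in genomic order. This makes the published-style names
  deterministic.

## Differential expression

The test machinery is the classic count-based recipe, self-contained:

* **Size factors**: median-of-ratios, `ŝ_l = median_f k_fl / gm_f` over
  features positive in every library (per-library fallback otherwise,
  logged). Factors are relative; scaling one library scales its factor
  relative to the others and leaves all normalized ratios invariant.
* **NB test**: two-group comparison on the group sums `K_A, K_B`. The common
  normalized mean is estimated from the pooled data; each group sum is
  modeled NB with mean `q·S_g` and variance `q·S_g + α q² Σ_j s_j²`. The
  p-value conditions on `K_A + K_B`: every split is enumerated and the
  probabilities of splits no likelier than the observed one are summed
  (min-likelihood two-sided rule), exactly for totals ≤ 10⁴ and by a
  conditional normal approximation beyond. At α = 0 the test reduces exactly
  to the conditional binomial test (verified to 10⁻⁶ in the suite).
* **Dispersion**: method of moments. The per-feature estimator
  `max(0, (s² − μ̄)/μ̄²)`, pooled across replicate groups and floored at
  `min_dispersion = 0.01`, is exposed but too noisy at 2–3 replicates to
  yield a calibrated test. `call_de` therefore defaults to a **pooled**
  estimator shared across features (ratio of means of within-group excess
  variance over squared means), which recovers a common dispersion
  accurately when many features are available. This borrows the
  information-sharing idea of local-regression dispersion fitting in a
  simpler, fully specified form. Type-I error under the null design
  (2,000 features, α_true = 0.05, n = 3) stays within 3 standard errors of
  the nominal 0.05 across seeds; power for a 4-fold effect at mean 200 is
  ≈ 1.
* **Multiple testing**: none by default — calls use raw `p ≤ 0.05`, matching
  the thresholding convention of the analysis this package models. A
  Benjamini–Hochberg flag exists for users who want FDR control.
* **Contrast grid**: pairwise per time point against the matched-time
  control, one test per (stressor, dose, time). Missing control time points
  skip the contrast with a log message. Pooling time points as replicates
  within a stress level is deliberately *not* the default.

## Expression patterns

Ratio matrices are `log2((m_stress + c)/(m_control + c))` on normalized group
means with pseudocount `c = 1` to handle zeros. Clustering defaults to
1 − Pearson correlation distance with average linkage (both configurable;
Euclidean available) and a cut at `k = 4` clusters, the granularity at which
up-, down-, delayed- and strongly-down patterns separate in this kind of
data. Constant rows get distance 1 to all others (zero-variance guard,
logged). SciPy's linkage resolves distance ties by lowest index, so results
are deterministic for a fixed row order and invariant to permutation up to
relabeling. Percentile ranks are within-library ascending ranks of
normalized counts mapped to `100·(r−1)/(n−1)`, ties averaged; a one-feature
matrix ranks 100 by convention.

## Sequence characterization

* **Terminator detection** enumerates every (start, stem length 6–12, loop
  3–10) placement, requiring ≤ 1 non-pairing position (G:U wobble allowed,
  configurable), and scores
  `paired + 0.5·GC_pairs − mismatches + min(u_tail, 8)` with default
  acceptance at score ≥ 8. The U tail is the longest U run starting within
  3 nt of the stem's 3' end. Overlapping placements are resolved greedily by
  score (ties: leftmost, shorter stem, shorter loop), so one hairpin is
  reported once. The detector deliberately ignores thermodynamics: no
  partition function, no free-energy model. The pairing-count score is fully
  enumerable and therefore exactly testable against a brute-force oracle,
  which is the property this package needs; it will rank unusual but
  thermodynamically stable structures differently than a folding engine
  would.
* **Hfq-target model**: positive iff (a) a terminator lies in the 3' half of
  the sRNA (stem-loop midpoint at or past the sequence midpoint), (b) ≥ 5 U
  within the 10 nt downstream of the stem, and (c) the 25 nt upstream of the
  stem is U-rich (≥ 0.40) or AU-rich (≥ 0.70). All five thresholds are this
  package's declared defaults for the qualitative published description of
  the motif; they are exposed in `HfqParams`. Windows truncated by sequence
  ends are evaluated as-is and flagged low-confidence.
* **Promoter PSSMs**: log2-odds with pseudocount 0.5 against a declared
  background (uniform by default), two-box scan with spacer 15–19 nt (a
  σ^A-like default; the spacer range is configurable). Scores are additive
  and translation-invariant; the scan is verified against exhaustive
  placement scoring.

## Synthetic data generator

The generator emulates the study design the analysis assumes:

* **Genome**: one contig of alternating inter-operon gaps (500–900 nt) and
  operons of 1–5 ORFs (300–900 nt each), i.i.d. sequence at GC 0.29. Two
  highly expressed singleton-operon genes stand in for structural RNAs.
  Defaults: 60 operons, 20 novel sRNAs (48–300 nt, ≥ 80 nt when carrying the
  Hfq cassette), 8 known sRNAs, 10 UTR decoys, 5 spurious predictions.
* **Planted sRNAs** sit centrally in distinct gaps with ≥ 60 nt clearance
  from both flank windows. Half (configurable) receive a spliced 3' cassette:
  25 nt U/A-rich tract, 8 bp GC-rich stem, 4 nt loop, 8 nt poly-U tail.
  Because the genome is AT-rich, chance hairpins with U runs occur; the
  generator therefore *verifies its labels at construction*: negatives are
  resampled until the Hfq classifier rejects them, and positives are
  resampled until the cassette is the classifier's selected terminator
  (flanking sequence can otherwise form an equally scoring overlapping stem
  whose tail is not the poly-U tract). Planted labels are thus separable at
  the default thresholds by construction — the end-to-end Hfq check
  validates the plumbing, not the biological discriminability of the motif.
* **UTR decoys** occupy one 50-nt flank window of a gap abutting an ORF
  whose baseline is forced ≥ 250 expected counts. Decoy reads straddle the
  ORF boundary so that the decoy's IOR-side coverage falls entirely inside
  the flank window — the coverage shape of a transcript bleeding out of a
  gene end. Reads never extend more than read_length − 1 nt beyond the
  window (on the ORF side).
* **Counts**: NB with variance `μ + αμ²` (α default 0.05 — a modeling
  choice, not an estimate from any dataset), library size factors lognormal
  (σ = 0.15) around 1, feature baselines rescaled to sum to the per-library
  depth. ORF baselines are lognormal (median 250, σ_log = 0.8); sRNAs
  uniform 200–600; decoys 200–400. Stress effects are multiplicative and
  dose-monotone (fold 1.5/2/4 at low/medium/high), sign-mixed across sRNAs,
  with 80% of planted sRNAs responsive to one or both stressors, and ramp in
  over the first sampling interval (exponent 0.5 at 15 min, 1 thereafter).
  Background noise is Poisson at 0.5% of depth, uniform over the contig, so
  the count-50 threshold is exercised against a realistic floor.
* **Design**: 7 conditions (none; butanol and butyrate at low/medium/high
  = 30/60/90 mM and 30/40/50 mM) × 4 time points (15/30/60/75 min) × 2
  replicates at 50 k reads/library — a desk-scale replica of the original
  84-library layout (3 replicates, ~10⁷ mapped reads/library), sized so the
  full validation study runs in seconds.

What the generator does **not** emulate: sequencing error and quality,
rRNA-depletion artifacts, strand-specificity, operon misannotation,
transcription start/stop heterogeneity, correlated expression between
neighbors, or condition-dependent dispersion. Passing end-to-end tests
therefore demonstrates the correctness of the pipeline's logic under its own
model assumptions, not robustness to real-data pathologies.

## Numerical and determinism notes

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical config + seed reproduces every
  output byte-for-byte, verified by SHA-256 manifests over all emitted
  tables.
* The exact NB test enumerates splits with vectorized pmf evaluation;
  probability ties use a 1 + 10⁻¹⁰ relative guard so the observed split is
  always included.
* TSV output uses `%.6g` floats to keep hashing stable across runs.
* Degenerate inputs: all-zero features test at p = 1; empty read sets give
  zero coverage; an IOR shorter than the flank window is never auto-
  eliminated; single-feature percentile ranks are 100 by convention.

## Problem sizes used in validation

The shipped validation runs are sized for a laptop-class single core: the
end-to-end study uses 56 libraries × 50 k reads (~2.8 M read intervals,
~3 s), the null calibration 2,000 features × 6 libraries, and the power
study 100 repeats; the oracle-equivalence checks use 100 randomized fixtures
per operation at ≤ 10³–10⁴ reads and ≤ 300 nt sequences. All scale linearly
if enlarged.
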