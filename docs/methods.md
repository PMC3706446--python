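# Methods

## Study design and measurement model

The package analyses tag-count RNA-seq of purified zebrafish pigment cells
— melanocytes, iridophores, retinal pigmented epithelium (RPE) — against
pooled whole 3 dpf embryos.  The canonical design is 11/5/5 biological
replicate libraries for the three cell types and 3 pooled embryo libraries
over a ~25,102-gene non-redundant transcript universe.  Expression is
RPKM, computed exactly as `count / (length_bp/1000) / (library_total/1e6)`
with the library total being uniquely mapped reads; this satisfies the
conservation identity `sum_genes rpkm * length_kb * total/1e6 = column tag
count`, which the tests verify to 1e-6 relative error.

Cell-type profiles are unweighted arithmetic means of per-library RPKM
(averaging RPKM, not pooling counts, so each biological replicate carries
equal weight regardless of depth).

## Non-redundant transcript database

Public cDNA collections carry near-identical records that defeat unique
tag assignment.  The collapse rule: for every transcript pair with a
similarity hit of **greater than 94% identity over more than 70% of the
shorter sequence's length**, remove the smaller transcript.  Decisions made
here where the rule is underdetermined:

- *Which transcript anchors the 70% coverage?*  The shorter one — the
  reading consistent with removing the smaller record.  Exposed as
  `coverage_ref = shorter|longer|subject`.
- *Inequalities* are strict, as worded (">94%", "more than 70%").
- *Order of removals.*  Pairs are processed greedily in a deterministic
  order: descending identity, then descending alignment length, then id
  order; a pair is skipped when either member is already removed, so a
  removed transcript never causes removals.  This makes the kept set a
  fixpoint (idempotent under re-collapse) and independent of input hit
  order.  Length ties drop the lexicographically larger id.
- Asymmetric hits for the same pair are merged keeping the max-identity
  record.

For desk-scale sets without an external BLAST run,
`all_vs_all_identity` computes best Smith–Waterman local alignments
(match +1, mismatch −1, gap −2, configurable) via Biopython's
`PairwiseAligner`, with identity = matches / alignment columns.  Pairs
whose best local score is below `min_score` (default 10) are not reported;
this mirrors the behaviour of a seeded heuristic search, which produces no
hit between unrelated sequences, and prevents meaningless 1-bp "100%
identity" alignments between random sequences from entering the collapse.

## Detection and saturation

A gene counts as expressed at threshold θ (default 1 RPKM) inclusively
(mean RPKM ≥ θ); the threshold's verbal definitions alternate between "at"
and "above", and the inclusive reading is exposed as a flag.  Saturation
curves rarefy each library's *aligned tags* (not raw reads) without
replacement to a ladder of depths and re-apply θ with the subsampled total
as the RPKM denominator.  Subsampling is implemented as one random
permutation of the library's tags per (seed, library), taking prefixes, so
subsamples at increasing depth are nested by construction and the curves
are monotone per seed in practice.  (Gene-level detection under a
depth-rescaled RPKM threshold is not formally monotone — a borderline
gene's RPKM can drift under the threshold as depth grows — but with
depths spaced by decades the aggregate counts rise monotonically.)

## Differential statistics

- **t-test**: equal-variance (pooled) two-sample Student's t on linear
  RPKM across replicate libraries, df = nA + nB − 2, two-sided p.
  Degenerate contracts: both groups constant and equal → t = 0, p = 1;
  both constant and unequal → infinite t, p = 0 with a warning.  A
  log-scale variant is available but off by default.  **No
  multiple-testing correction is applied anywhere**: the enrichment
  filters gate on raw p < 0.05 by design, and the published lists are only
  reproducible under that convention.
- **Fold changes**: x/0 = +inf (passes any ≥ k threshold), 0/0 =
  undefined (fails every threshold), matching how zero-embryo genes behave
  in the published tables.  Quoted folds are truncated to whole folds at
  ≥ 1 (71.28 → 71, 198.64 → 198) and rounded to one decimal below 1 —
  the convention the published prose follows.
- **Embryo comparisons are fold-only.**  The pooled whole-embryo libraries
  have no biological replicate structure, so no p-value is attached to any
  embryo criterion.
- **Windowed correlation**: genes sorted by ascending embryo mean (stable
  sort, gene id as tiebreak — many genes share 0.00), Pearson r per
  overlapping window of w = 1000 genes, averaged unweighted across
  windows.  The window count is `n_genes − w` (24,102 windows at 25,102
  genes): the last possible start is excluded, matching the published
  window arithmetic.  Zero-variance windows yield a flagged NaN excluded
  from the average.  The implementation centres each vector globally and
  uses sliding sums; it agrees with a direct per-window loop to better
  than 1e-12.  Type-averaged RPKM feeds the windows (per-library input
  would also be possible; the published axes do not distinguish them).

## Enrichment classification

All published gene lists are conjunctions evaluated per gene on the
averaged profile:

| preset | shape | thresholds |
|---|---|---|
| `shared_identity` | shared_all | within 2-fold, ≥ 4 RPKM, ≥ 100× embryo |
| `mel_rpe_shared`, `mel_irid_shared`, `rpe_irid_shared` | pairwise | ≥ 2× third type (p < 0.05 each), ≥ 8× embryo |
| `mel_specific`, `irid_specific`, `rpe_specific` | specific | ≥ 2× both others (p < 0.05 each), ≥ 8× embryo |
| `mel_rpe_stringent` | pairwise, no p | ≥ 10× iridophore, ≥ 10× embryo, ≥ 10 RPKM |
| `mel_irid_stringent` | pairwise, no p | ≥ 5× RPE, ≥ 10× embryo |
| `irid_stringent` | specific, no p | ≥ 30× mel and RPE, ≥ 100× embryo |

Interpretation decisions, each verified against every printed table row
(no printed row is excluded by these readings) and exposed as
configuration:

- "at least k-fold" is inclusive (≥ k); "within a 2-fold change" is
  max/min ≤ 2.
- The embryo-fold criterion applies to **every** target cell type
  (`embryo_rule="min"`, the strictest reading; `max`/`any` relax it).
- The p criterion applies to **each** fold comparison of the shape (both
  comparisons for specific genes, each target-vs-third for pairwise).
- The pathway report flags significance at p < 0.01 for the
  iridophore-vs-melanocyte and iridophore-vs-RPE columns.

The stringent table presets keep the pairwise/specific shapes with the p
criterion disabled, as their captions state only folds and floors.  When a
published table shows only the "most highly expressed" members of a larger
set, this package sorts candidates by max(melanocyte, RPE) descending; the
original secondary sort is unstated.

## Synthetic data generator

The generator exists so that every downstream stage has exact ground
truth.  It emulates the canonical design above; what it does **not**
emulate: read-level errors and alignment ambiguity, batch or lane effects,
developmental-stage drift between libraries, and gene–gene correlation
beyond the planted class structure.  Passing parameter-recovery tests
therefore demonstrates the statistical machinery under the declared noise
model, not robustness to artefacts absent from that model.

- **Class mixture** (defaults): background 57%, housekeeping 20%,
  unexpressed 13%, shared_all 1%, each pairwise class 1%, each specific
  class 2% — planted classes deliberately generous relative to the real
  lists (tens to hundreds of genes) so recovery rates are estimable.
- **Baselines**: log-normal with σ = 2 (heavy-tailed, decades of dynamic
  range).  The location is calibrated analytically so the expected
  fraction of genes at ≥ 1 RPKM per cell type hits the 0.35 target
  (configurable), consistent with roughly a third of the genome being
  appreciably expressed per cell type.  Housekeeping baselines are
  truncated at 1 RPKM; enriched-class baselines at `4 × fold_margin` RPKM,
  tied to the shared-identity filter's 4-RPKM floor.
- **Enrichment multipliers**: target classes get
  `threshold × fold_margin × exp(Exponential(ln 2))` — a heavy-tailed
  excess above the defining threshold, because real enriched genes span
  5- to 400-fold, not a point mass at the cutoff.  shared_all classes
  jitter all three cell types within a 1.35× band (inside the 2-fold
  criterion with room for sampling noise).
- **Embryo mixture**: embryo mean = `pf × mean(cell-type means) + (1−pf) ×
  bulk`, with pigment fraction pf = 0.005 (pigment cells are <1% of the
  embryo) and bulk = baseline for background/housekeeping genes, 0 for
  planted pigment genes.  Planted pigment genes are thereby diluted
  ~150–600-fold versus embryos, matching the observed dilution regime, and
  background genes sit at ~1× embryo so they can never leak through an
  embryo-fold criterion.
- **Counts**: negative binomial with mean
  `baseline × multiplier × length_kb × total/1e6` and dispersion α = 0.2
  (variance m + αm²), the standard overdispersion model for tag counts;
  α = 0 falls back to Poisson.  Gene lengths are log-normal, median 2 kb,
  clipped to [200, 50000] bp, and carried explicitly so RPKM is exact.
  Library depth defaults to 3×10⁶ declared reads; expected aligned tags
  run well below the declared totals, as in real tag libraries where many
  reads fail to assign uniquely.
- **Embryo replicates** default to 3 pooled libraries (the real design
  pooled one library with technical replicates; the count is exposed in
  the design).
- **Redundant transcripts**: each cluster is a random root sequence plus
  truncated (75–97% of full length), point-mutated copies; the root is the
  planted representative.  At 1% mutation within-cluster identity is ~98%
  over ~full coverage of the shorter member, comfortably inside the
  collapse rule; at 10% it falls below the 94% threshold and the collapse
  correctly keeps both.

All draws derive from a single root seed (split into fixed substreams for
truth, counts, and transcripts), so identical seeds give byte-identical
outputs including FASTA bytes.

## Problem sizes used in the test suite

The acceptance-style tests run the full canonical design (25,102 genes,
24 libraries) for parameter recovery over 20 seeds, a 5M-read library for
the saturation check, 2,000-gene profiles for the windowed-correlation
oracle (with one full-width 25,102-gene window-count check), and 30-cluster
transcript sets over 10 seeds for collapse recovery.  These sizes keep the
suite to a few minutes on one CPU while leaving every statistical margin
(sensitivity ≥ 0.90, FDR ≤ 0.10, ≥ 95% representative recovery, ≥ 95%
detection at 1M reads) comfortably non-marginal.

## Known limitations

- The full-study headline counts (214 melanocyte+RPE genes, 62
  melanocyte+iridophore, 1 RPE+iridophore, 8,472 melanocyte-expressed)
  require the study's full averaged-RPKM supplementary profile, which is
  not redistributable inside this repository; the corresponding check runs
  only when that profile is supplied at `data/supplementary/profile_s5.tsv`.
- `all_vs_all_identity` is exact quadratic dynamic programming — intended
  for hundreds of sequences, not the ~28k of a full cDNA database; for
  full-scale collapses, feed an external BLAST tabular file.
- The t-test operates on linear RPKM with equal-variance pooling, as the
  published lists require; it is anti-conservative under strong
  heteroscedasticity and should not be re-used as a general-purpose DE
  method (use a count-based framework for that).
- The original 28,286 → 25,102 record reduction depends on the 2013 NCBI
  cDNA snapshot and is not reproducible from this package alone.
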