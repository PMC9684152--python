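# Methods

## Problem setting

A taxon-by-sample 16S count table with Greengenes-style lineages, plus
per-sample categorical factors (host species, developmental stage, sex,
geographic area, collection site), is analyzed to decide whether — and at
which taxonomic rank — the gut community predicts a host's geographic
origin. Geography is a minor driver of community composition relative to
host species, so the pipeline is built around a supervised projection
(Fisher LDA) rather than unsupervised ordination.

## Feature construction

Counts are aggregated to each rank (phylum … species) by summing child
taxa; taxa lacking a name at a rank go to an explicit `Unassigned` bin so
per-sample totals are conserved exactly in integer arithmetic. Lineage
parsing enforces the prefix property: once a rank is missing, deeper ranks
are truncated. Feature matrices for ordination are relative abundance
(computed on the full column including the unassigned bin, so compositions
reflect true totals), optionally log-transformed as `ln(rel + ε)`.

- **ε = 1e-6 (default).** Below the smallest observable relative abundance
  at the modeled depths (1/150,000 ≈ 6.7e-6), so it never reorders observed
  abundances; natural log, since any fixed base only rescales LDA inputs
  linearly.
- The `Unassigned` feature itself is excluded from ordination input: it
  encodes annotation quality, not biology.

## Ordination and classification

**PCA** is the SVD of the centered (optionally unit-scaled) matrix; scores,
per-axis variance fractions and loadings are returned, and reconstruction
from all axes reproduces the centered matrix to machine precision.

**LDA** solves `B v = λ (W + reg · tr(W)/p · I) v` with `W` the pooled
within-class scatter and `B` the between-class scatter of class means,
keeping at most `g − 1` axes (fewer if `B` is rank-deficient). Scalings are
normalized so the within-class covariance of the scores is the identity.

- **reg = 1e-6 (default).** Taxon tables are routinely `p ≫ n`; a ridge
  proportional to the mean within-class variance `tr(W)/p` makes the
  eigenproblem well posed with a data-independent scale. Zero-variance
  features are removed before fitting (their scaling rows are zero).
  With `reg = 0` and full-rank `W`, classifications are invariant under any
  invertible affine feature rescaling.
- **Classification** uses the equal-covariance Gaussian rule in score
  space, `posterior ∝ prior · exp(−½‖score − centroid‖²)`, with empirical
  class frequencies as priors and ties broken toward the
  earlier-registered class. With all `g − 1` axes retained this equals the
  pooled-covariance Gaussian classifier in the original feature space
  (verified against a brute-force oracle in the tests).

## Accuracy and level selection

Accuracy is resubstitution: fit on the labeled samples, classify the same
samples, report the matching fraction. Stability is probed by:

- **Jackknife** — per replicate, drop `max(1, round(0.15 · n_g))` samples
  uniformly from every class `g` (stratified; the `max(1, ·)` guard ensures
  every class is perturbed), refit, and score. Scoring is resubstitution on
  the retained samples by default; scoring the dropped samples instead is
  available (`score_heldout=True`) since "accuracy under deletion" admits
  both readings.
- **Bootstrap** — per replicate, draw `n` samples with replacement
  (unstratified); draws in which any present class has fewer than two
  members, or fewer than two classes appear, are redrawn (count recorded),
  since the discriminant is undefined there.

Both default to 1000 replicates. A single user seed spawns one independent
substream per replicate (`numpy.random.SeedSequence`), so results are
reproducible and replicate-order independent. Rank selection: ranks whose
jackknife **and** bootstrap mean accuracies are ≥ 0.95 (default threshold),
ordered by descending mean and ascending pooled SD.

## PERMANOVA

Squared distances are partitioned as `SS_total = Σ_{i<j} d²_ij / n`,
`SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g`, `SS_between` by difference;
`pseudo-F = (SS_between/(g−1)) / (SS_within/(n−g))`, `R² =
SS_between/SS_total`. The p-value permutes labels uniformly with the +1
convention `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`; an exhaustive
enumeration mode (all `n!` permutations, `n ≤ 9`) exists for exact
small-sample checks. With Euclidean distance on one variable the pseudo-F
equals the classical one-way ANOVA F.

- **Defaults:** Bray-Curtis on abundance tables, Euclidean on ordination
  coordinates; 999 permutations (p-resolution 0.001). Both are recorded in
  every result.
- **Effect sizes** are marginal: one single-factor PERMANOVA per factor on
  the same distance matrix, reported in descending R². Samples missing a
  factor's level are excluded from that factor's test only.
- **LDA vs PCA:** for each of `n_subsamples = 20` stratified subsamples
  (fraction 0.85 per class), both methods are fitted and the PERMANOVA R²
  of the labels on each method's first-two-axes Euclidean distances is
  computed; a paired two-sided t-test across subsamples summarizes the
  contrast. The repeated-subsample pairing is this package's documented
  convention for an otherwise under-specified comparison. First-two-axes
  scoring matches the visualized space; full-space distances are available.
- Degenerate input (all samples identical) reports NaN F, R² = 0, p = 1
  rather than failing.

## Alpha diversity

Shannon (natural log), Gini-Simpson `1 − Σ p²` (the bounded [0,1] variant),
bias-corrected Chao1 `S_obs + F1(F1−1)/(2(F2+1))` (defined at `F2 = 0`),
and Faith's PD (total branch length spanning root and present taxa; index
values computed through scikit-bio). No rarefaction is applied; per-sample
depth is returned alongside the indices so depth confounding stays
inspectable. Group comparisons use the two-sided rank-sum test — exact
enumeration when both groups have ≤ 10 samples, normal approximation
otherwise — with no multiple-testing correction (flagged in the output).

## Synthetic-data generator

The generator emulates the *structure* of a multi-host biosurveillance
study: `n` host species each collected in a subset of geographic areas
(sites nested in areas, 2 per area), balanced cells, depth uniform in
50,000–150,000 reads. Per-sample log abundance over the leaf taxa is

```
η = baseline + species_shift + stage_shift + sex_shift + geography_shift
```

with i.i.d. Gaussian shift vectors whose standard deviations are the
factor effect sizes, defaults **species 1.0 > stage 0.55 > geography 0.35 >
sex 0.15** — ordering chosen to reproduce the qualitative dominance
hierarchy such studies report. The geography shift is constant within
blocks of taxa sharing a name at `signal_rank` (default `class`), so the
geographic signal is exactly recoverable at that rank and dilutes under
coarser aggregation. Composition is `softmax(η)` perturbed by a Dirichlet
draw with concentration 500 (a mild-overdispersion convention; the true
overdispersion of real surveys varies widely), and counts are multinomial.

The default taxonomy shape (40, 98, 178, 277, 598, 900 names at phylum …
species) mirrors the breadth of a broad 16S survey; every leaf carries a
complete 7-rank lineage and the accompanying tree is ultrametric with the
taxonomy as its topology (equal height steps per rank; the root is made
bifurcating with two zero-length children, as rooted-tree PD requires).

**What the generator does not emulate:** unbalanced and confounded designs,
rank-incomplete annotations, taxon-taxon correlation beyond the shared
block shifts, batch effects, and sequencing error. Tests passing on this
generator therefore demonstrate correctness of the estimators and the
recoverability logic, not performance on real surveys.

## Problem sizes used in tests and reproduction runs

Tests and `scripts/acceptance.py` run a desk-scale configuration of the
same design (the `paperlike-mini` preset): 8 host species × 4 of 5 areas ×
3 samples = 96 samples, taxonomy shape (6, 12, 20, 32, 48, 72), 50
resampling replicates, 199 permutations; parameter-recovery checks use 20
generator seeds and report modal outcomes. The full-scale `paperlike`
preset (22 species, ~900 leaf taxa, 1000 replicates, 999 permutations) is
the package default for real use.

## Numerical conventions

- Eigenvalue rank detection uses a relative threshold of 1e-9 on the
  leading generalized eigenvalue.
- Posterior computation subtracts the row-max log posterior before
  exponentiating; rows sum to 1 to 1e-12.
- Classifier ties and duplicate-lineage aggregation are deterministic
  (first-registered class wins; duplicate lineages are summed, never
  averaged).
- All resampling and permutation seeds derive from one user seed via
  `SeedSequence` spawning; every result object records the seed and
  parameters that produced it.

## Known limitations

- Resubstitution accuracy is optimistic (order `p/n` at the null); the
  held-out jackknife scoring mode exists precisely to quantify that gap.
- PERMANOVA here is one-factor (marginal); sequential/partial
  decompositions and dispersion diagnostics are out of scope.
- The rank-sum comparison of alpha diversity is uncorrected by design;
  apply a correction downstream when screening many group pairs.
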