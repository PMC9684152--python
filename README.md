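# gutrace

Geographic traceability of insect hosts from their gut-microbiota
composition.

Invasive (quarantine) insects intercepted at ports need a fast answer to
"where did this individual come from?". Because an insect's gut bacterial
community reflects its environment, the 16S profile of its gut can act as a
geographic fingerprint — but the signal is weak relative to host-species
differences, so unsupervised ordination (PCA) fails while supervised linear
discriminant analysis (LDA), given geographic labels as prior information,
succeeds. `gutrace` implements that analysis end to end for
microbiome/biosurveillance researchers:

- **taxonomic aggregation** — Greengenes lineage parsing and per-rank
  (phylum … species) count tables with exact total conservation;
- **ordination** — PCA by SVD, and multiclass Fisher LDA solving
  `B v = λ (W + reg·tr(W)/p·I) v` for within-/between-class scatter `W`,
  `B`, with a nearest-centroid Gaussian classification rule
  `P(g|x) ∝ π_g exp(−½‖score(x) − centroid_g‖²)`;
- **traceability evaluation** — the accuracy statistic (fraction of samples
  the fitted discriminant assigns to their own labels), its stratified
  jackknife (drop ~15% per class, refit, 1000×) and bootstrap (n with
  replacement, 1000×) distributions, and selection of the taxonomic ranks
  whose jackknife *and* bootstrap mean accuracies clear 0.95;
- **PERMANOVA** — pseudo-F = `(SS_B/(g−1)) / (SS_W/(n−g))` on Bray-Curtis
  or Euclidean distances with permutation p-values, per-factor effect sizes
  (R²), and a paired t-test contrasting group separation in LDA vs PCA
  score space;
- **alpha diversity** — Shannon, Gini-Simpson, bias-corrected Chao1, and
  Faith's PD, with pairwise rank-sum group comparisons;
- **a synthetic-community generator** — Dirichlet-multinomial counts over a
  nested 7-rank taxonomy with additive log-scale effects for host species,
  developmental stage, sex, and geography (geography injected at a chosen
  rank), so every claim the pipeline makes is testable against known ground
  truth.

## Worked example

Simulate a desk-scale study — 8 host species collected from 4 of 5
geographic areas, 96 samples, 72 leaf taxa, sequencing depth 50,000–150,000
reads — with a strong geographic signal injected at the class rank, then ask
which taxonomic level carries the geographic information:

```python
from gutrace import (SimulationSpec, simulate_dataset, build_rank_set,
                     evaluate_levels, factor_effect_sizes)

spec = SimulationSpec(
    n_host_species=8, taxonomy_shape=(6, 12, 20, 32, 48, 72),
    samples_per_cell=3, areas_per_species=4,
    effect_geography=3.5, signal_rank="class", seed=7)
ds = simulate_dataset(spec)
ranks = build_rank_set(ds.table)
report = evaluate_levels(ranks, ds.metadata, "geographic_area",
                         reps=200, seed=7)
```

This prints (via `report.summary_rows()`):

```
  phylum  resub=0.979  jk=0.979+/-0.006  bs=0.987+/-0.009
   class  resub=1.000  jk=1.000+/-0.000  bs=1.000+/-0.000
   order  resub=1.000  jk=1.000+/-0.000  bs=1.000+/-0.000
  family  resub=1.000  jk=1.000+/-0.000  bs=1.000+/-0.000
   genus  resub=1.000  jk=1.000+/-0.000  bs=1.000+/-0.000
 species  resub=1.000  jk=1.000+/-0.000  bs=1.000+/-0.000
selected levels: ['class', 'order', 'family', 'genus', 'species', 'phylum']
```

The class rank — where the signal was injected — classifies every sample
to its true area with zero resampling variance and tops the selection; the
phylum rank, where aggregation partially cancels the class-level shifts,
scores lower. Per-factor PERMANOVA effect sizes on the same data
(`factor_effect_sizes`, Bray-Curtis, 999 permutations):

```
       geographic_area  R2=0.706  F=54.54  p=0.001
        insect_species  R2=0.155  F=2.30  p=0.002
   developmental_stage  R2=0.021  F=2.04  p=0.078
                   sex  R2=0.014  F=1.35  p=0.219
```

R² is the fraction of distance-based community variance a factor explains;
here the inflated geography effect dominates, and sex — the weakest
generator effect — is indistinguishable from noise.

The same stages are available from the shell:

```sh
gutrace simulate --preset paperlike-mini --seed 7 --out sim/
gutrace evaluate --table sim/taxon_table.tsv --metadata sim/metadata.tsv \
    --label geographic_area --reps 1000 --seed 7 --out levels.tsv
gutrace run --preset paperlike-mini --seed 7 --out results/
```

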