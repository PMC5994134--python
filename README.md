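# ecoscope

Phylogeny-aware community ecology for clone-library compilations: a tested,
reusable implementation of the statistical workflow used to characterise the
global distribution of an archaeal phylum (Woesearchaeota-style surveys)
across heterogeneous biotopes.

The package targets the common situation in microbial biogeography where the
raw data are a library × taxon abundance table compiled from many published
clone libraries, a rooted 16S phylogeny, per-library environmental
descriptors, and a taxon → lineage map.  It provides, end to end:

- **Diversity and phylogenetic structure** — Faith's PD (rooted convention)
  with randomized subsampling, phylogenetic species variability
  `PSV = (n·tr C − ΣC) / (n(n−1))` on the tip correlation matrix with two
  community-null models (occurrence-preserving and richness-preserving), and
  unweighted UniFrac (unique / total spanned branch length).
- **Ordination and variance partitioning** — Bray-Curtis dissimilarities,
  principal coordinates, permutational MANOVA (pseudo-F over seeded label
  permutations), environmental-factor fits on ordination axes, and
  rarefaction curves.
- **Lineage abundance distributions (LAD)** — occupancy-based core/satellite
  classification (core: detected in > 90 of 133 libraries; satellite: < 50)
  and the index-of-dispersion test: `D = s²/x̄` over occupied libraries,
  with `D·(n−1)` referred to the χ²(n−1) 2.5 / 97.5 % confidence limits to
  separate randomly placed (Poisson) lineages from aggregated ones.
- **Co-occurrence networks** — Spearman rank correlations over all retained
  libraries, the `ρ > 0.6, P < 0.01` reliability filter, and random-matrix
  theory threshold selection: the correlation threshold at which the
  nearest-neighbour spacing distribution of the unfolded eigenvalue spectrum
  transitions from the Wigner surmise (GOE, correlated noise) to the Poisson
  law (decoupled signal blocks), plus topology indices and greedy modularity.
- **Ancestral state reconstruction** — two-state (1 = oxic, 2 = anoxic)
  Mk-model likelihoods via Felsenstein pruning with the closed-form 2-state
  transition matrix, ML rate fitting, and exact marginal node posteriors.
- **Indicator analysis** — IndVal (`100 × specificity × fidelity`) with
  permutation p-values, and a multivariate regression tree on environmental
  categories minimising within-node community sum of squares.
- **Synthetic data with ground truth** — a community generator that emulates
  the compiled survey (133 libraries across 7 biotopes, 6 aggregated
  negative-binomial core lineages, 40 Poisson satellite lineages, OTUs
  nested in lineages, planted correlated OTU pairs, traits evolved on
  simulated trees), so every stage has a recovery test.

## Worked example

```python
from ecoscope import synthetic_data as sd, lad

spec = sd.CommunitySimSpec(seed=1)           # the default study conditions
table, metadata, taxonomy, truth = sd.simulate_community(spec)
df = lad.lad_table(table, taxonomy)
print(df.loc[["core01", "core02", "sat01", "sat02"],
             ["occurrence", "mean", "dispersion", "statistic", "upper", "call", "class"]])
```

prints

```
         occurrence   mean  dispersion  statistic   upper        call      class
lineage
core01          110  21.97        9.17     999.40  139.78  non-random       core
core02          100  17.53        5.59     553.77  128.42  non-random       core
sat01            22   1.18        1.14      24.02   35.48      random  satellite
sat02            33   1.14        0.40      12.85   49.48      random  satellite
```

`occurrence` is the number of libraries where the lineage was detected,
`mean` its mean relative abundance (%) over those libraries, `dispersion`
the variance-to-mean ratio `D`, and `statistic = D·(n−1)` is compared with
the upper χ² confidence limit: the two core lineages are far above it
(aggregated, non-randomly distributed), while the satellites sit inside the
Poisson band.  On this seed the classifier recovers all 46 planted
core/satellite labels.

The same analyses run from the shell:

```bash
ecoscope simulate --seed 1 --out data/
ecoscope run-all --config config.yaml
```

`run-all` executes validate → diversity → ordination → LAD → network → ASR
→ indicators from one YAML config, writing TSV/newick/GraphML outputs, a
`summary.json` of key numbers, and a frozen config echo; identical inputs,
config, and seed give byte-identical summaries.

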