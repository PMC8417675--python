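# carepath

Prenatal care-pathway analysis for postpartum depression (PPD): cluster
pregnant patients by the similarity of their prenatal clinical event
sequences, mine the sequential care patterns within each cluster, quantify
the built environment around each patient's home, and link the three with a
recursive path model.

The package is written for epidemiologists and health-services researchers
who want to reproduce or extend this style of analysis. Real obstetric EHR
and municipal spatial data are protected, so a first-class synthetic-data
generator produces a complete study — patients, coded event sequences with
latent cluster structure, spatial layers, census-tract attributes, and
outcomes — with the statistical structure the analysis assumes, and every
stage is validated against independent oracles on that synthetic study.

## Methods at a glance

- **Sequence similarity.** Patient sequences of coded clinical events
  (encounters, SNOMED-like diagnoses, ATC-class-like medications, ordered by
  day relative to delivery) are compared with the longest common
  subsequence: `d(a, b) = 1 − LCS(a, b) / max(|a|, |b|)`, a dissimilarity in
  [0, 1].
- **Clustering.** Average-linkage agglomerative clustering on the pairwise
  LCS distance matrix; the number of clusters k maximizes the mean
  silhouette width `s(i) = (b(i) − a(i)) / max(a(i), b(i))`.
- **Pattern mining.** A from-scratch SPADE miner (vertical id-lists,
  depth-first equivalence-class search with sequence- and itemset-extension
  joins) finds every pattern whose distinct-patient support is at least
  `⌈minsup · n⌉`, within each cluster, with per-pattern PPD/no-PPD splits.
- **Built environment.** Euclidean-buffer indicators at 500 m (bus stops,
  subway stations, intersections, bike-path length, green and sidewalk
  area, light/heavy vehicle-kilometers traveled), the entropy land-use-mix
  index `LUM = −Σᵢ pᵢ ln pᵢ / ln k`, retail floor-area ratio at 250 m, and
  census-tract joins (PM₂.₅, O₃, GINI, college %, poverty, uninsured %,
  food access).
- **Path model.** A recursive two-equation system with a categorical
  mediator: multinomial logit of cluster membership on built-environment
  and adjustment covariates (after MICE imputation and VIF > 10 screening),
  and binary logit of PPD on cluster indicators; odds ratios are
  exp(coefficients), pooled by Rubin's rules across imputations.

## Worked example

```bash
carepath run --out-dir run --seed 1          # full pipeline on the default
carepath report run                          # synthetic study (n = 2,000)
```

or, stage by stage, `python analysis/01_simulate.py` …
`python analysis/07_report.py`. With the default configuration and seed 1
the drivers print (abridged):

```
simulate: wrote 2000 patients and 29648 events to results/run/sim
cohort: kept 1948 of 2000 patients
clustering: selected k=3 (average linkage)
mean silhouette by k: {'2': 0.233, '3': 0.3, '4': 0.293, ...}
adjusted Rand index vs planted clusters: 0.989
cluster 2 — top patterns:
  ENC_ED  support=422 (97%), PPD 27/422
  DX_ANXIETY  support=399 (92%), PPD 23/399
outcome equation (PPD ~ cluster indicators), odds ratios:
 variable    or_      p
cluster_2 7.6577 0.0000
cluster_3 2.4273 0.0793
```

Read: the silhouette criterion recovers the three planted care-pattern
clusters almost exactly (ARI 0.989); the high-utilization cluster is
dominated by emergency-department visits and mental-health diagnoses; and
the outcome equation recovers odds of PPD elevated by roughly the planted
factors (6.3 and 2.43) relative to the routine-care reference cluster, at
this sample size with sampling noise.

## Layout

- `src/carepath/` — the library: `simdata`, `cohort`, `lcs`, `clustering`,
  `spade`, `builtenv`, `models`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the pipeline.
- `tests/` — unit, property and end-to-end recovery tests with their
  brute-force oracles.
- `docs/methods.md` — the full methods note (model assumptions, parameter
  defaults, numerical choices, limitations).
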