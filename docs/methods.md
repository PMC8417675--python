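# Methods

This note documents the models, the synthetic study the package generates,
the parameter defaults and the numerical decisions, in the package's own
terms. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis

The pipeline asks a mediation-style question about postpartum depression
(PPD): do patterns of prenatal care, summarized as clusters of similar
clinical event sequences, sit on the path between a patient's residential
built environment and her odds of a PPD diagnosis in the year after
childbirth? Each stage below is a library module; the pipeline composes
them over plain files.

### Cohort definition

Patients are retained when 18 ≤ age ≤ 45, at least one event falls in the
study window, and the home location is known. The window runs from one
year before pregnancy start to one year after delivery; pregnancy start is
anchored at `delivery − 7·gestational_week` days. Anchoring "one year
before pregnancy" at conception rather than delivery is a deliberate
reading of an ambiguous inclusion phrase and is exposed in the code as the
single place the window is computed.

PPD is positive iff a diagnosis with a code in the configured code set
occurs at `0 < t ≤ 365` days after delivery — "within one year" is read as
inclusive of day 365, and the boundary is tested explicitly. Trimesters
use completed-week conventions: weeks 1–13 from pregnancy start are T1,
14–27 T2, 28 to delivery T3; earlier events are pre-pregnancy, `t > 0` is
postpartum.

Sequences for clustering take prenatal events (`t ≤ 0`) restricted to a
configured token allow-list, ordered by day with same-day ties broken by
`(event_type, code)` lexicographically; duplicate same-day tokens collapse
to one. The tie-break and the collapse are determinism decisions: the
distance matrix must be reproducible from unordered event tables, and
mining event *types* rather than counts keeps repeated same-day orders
from inflating similarity.

### LCS distance and clustering

The similarity primitive is the longest common subsequence. The distance
is `d = 1 − LCS(a,b) / max(|a|, |b|)`; the normalizer is configurable
(`max`, `mean`, `sum`) because the source analyses of this kind rarely
state it. `max` is the default: it keeps d in [0, 1], and penalizes length
mismatch (a short sequence embedded in a long one is not "identical care").

Clustering is agglomerative with average linkage. Ward linkage assumes
squared-Euclidean geometry that LCS dissimilarities do not have, so average
linkage is the defensible default for arbitrary dissimilarities; the
linkage is configurable. The dendrogram is cut by merge count (the first
n − k merges) rather than by height because tied merge heights — common
with coarse LCS distances — can make a height threshold unable to realize
exactly k groups. k is selected over a default range 2–8 by mean
silhouette width computed from the precomputed distance matrix; singleton
clusters score 0; ties prefer smaller k.

The O(n²) pairwise matrix is exact (no approximate neighbor shortcuts);
the DP core runs under numba over integer-encoded padded sequences, which
keeps the n = 2,000 default study (≈2·10⁶ pairs) at desk scale.

### SPADE pattern mining

The miner is a full, from-scratch SPADE: the database is vertical (item →
(patient, time) occurrence lists), and patterns grow depth-first with two
joins — S-extension (a new element strictly later than an embedding of the
prefix) and I-extension (an item added to the last element at the same
time, in lexicographic order so each itemset is enumerated once). A
pattern node's id-list records *all* times at which an embedding can end,
which makes both joins exact. Support counts distinct patients once,
regardless of repeats; frequency means support ≥ ⌈minsup·n⌉.

Defaults: minsup 0.10 of the cluster, max pattern length 5 items,
I-extension enabled (the pipeline's synthetic sequences have unique event
days, so in practice reported patterns are single-item chains). Reported
patterns carry a PPD/no-PPD split of their supporting patients and export
to DOT for pathway diagrams. Output order (support descending, then
lexicographic) is part of the contract. Correctness is established by
exact equivalence with an exhaustive enumerate-and-count oracle on
hundreds of random databases, plus anti-monotonicity and
order-invariance property tests.

### Built-environment indicators

All geometry is planar, in meters; real longitude/latitude layers must be
projected upstream. Membership is the closed disc (distance ≤ r) so
boundary cases are deterministic. Polygon and polyline clipping
approximates the disc by a regular 128-gon; the resulting relative error
is below 0.1 % and is tested against Monte-Carlo and dense-sampling
oracles. Indicators: point counts (bus stops, subway stations,
intersections) at 500 m; bike-path length; green-space and sidewalk area;
VKT per vehicle class as Σ link volume × clipped length in km; the
entropy land-use-mix index with `0·ln 0 ≡ 0`, normalized by `ln k` where k
defaults to the configured taxonomy size (six classes), so sparse buffers
score low — the alternative, k = classes observed, is a config switch;
retail floor-area ratio at 250 m with the numerator the full floor area of
intersecting retail parcels (floor area is not spatially divisible), the
denominator the clipped retail land area, and 0 when no retail land is in
the buffer. A buffer with no parcel land has undefined LUM, reported
missing and passed to imputation.

### Statistical stage

Missing covariates are completed by chained-equation imputation (MICE):
initialize missing cells by sampling observed values, then sweep the
target columns with conditional draws — ordinary-least-squares prediction
plus residual-scale Gaussian noise for numeric columns, logistic-model
Bernoulli draws for binary ones — for 10 iterations, m = 5 independent
chains from split seeds. Observed cells are never altered, and a table
with no missing cells returns identical copies.

Multicollinearity is screened by iteratively removing the largest variance
inflation factor while any VIF = 1/(1 − R²) exceeds 10; exact ties (and
exactly collinear pairs) drop the later-listed variable for determinism.

The "structural equation model" is a generalized recursive path model with
no latent variables: (1) multinomial logit of cluster membership versus a
reference cluster on the mediator covariates, (2) binary logit of PPD on
the non-reference cluster indicators. Because the system is recursive and
fully observed, the joint likelihood factorizes and equation-by-equation
maximum likelihood is the joint ML — verified in the tests against a
direct joint-likelihood optimizer. Estimates across imputations pool by
Rubin's rules; tests and intervals are Wald; odds ratios are exactly
exp(coefficients). The pipeline's default reference cluster is the one
with the lowest observed PPD rate (the routine-care analogue); the
per-cluster comparison tables use Pearson chi-square without continuity
correction (so the statistic is exactly Σ(O−E)²/E) for categorical
variables and one-way ANOVA for continuous ones.

## The synthetic study

The generator is first-class, tested code; its defaults are the study
conditions everything downstream is validated under.

* **Cohort.** n = 2,000 by default; three latent clusters with mixing
  proportions (0.22, 0.46, 0.32), echoing the reported 1,934/4,129/2,886
  composition at reduced scale. Ages are Normal(33.7, 4.6) with a 2 %
  uniform(15, 49) outlier mass so the age filter has work to do; ~1 % of
  patients have missing home locations and ~1 % have all events outside
  the study window, for the other two filters. BMI carries 5 % MCAR
  missingness to exercise imputation. Marital status, race and insurance
  are drawn at the published cohort proportions.
* **Event sequences.** Per-cluster first-order Markov chains over a
  17-token vocabulary (encounters, diagnoses, medications). Each cluster
  up-weights an ordered "emphasis" list of tokens by a factor of 8 and
  walks along it with probability 0.5 per step, planting recurrent
  sequential motifs; all clusters share background mass on the full
  vocabulary, so separation is real but not trivial. Sequence length is
  1 + Poisson(13) events on distinct days in `[−7·gw, 0]`; ED encounters
  are added with cluster-specific means pre/post delivery, and
  PPD-positive patients receive a postpartum depression diagnosis event,
  so the cohort labeler recovers the planted outcome from the event table
  alone. The within-cluster variability of real prenatal care is not
  characterized in published work; these separation parameters are the
  package's own calibration, exposed in the configuration.
* **Geography.** A 6 km square region. Point layers are (optionally
  x-tilted) Poisson processes; parcels tile the region in 200 m cells
  whose land-use mix shifts along x from residential/industrial toward
  commercial/retail; tract attributes (PM₂.₅, O₃, GINI, college %,
  poverty, uninsured %) carry x-gradients plus noise. Cluster-specific
  Gaussian home placement along x (means at 0.25/0.5/0.75 of the region)
  is what plants built-environment → cluster associations for the
  mediator equation.
* **Outcomes.** PPD ~ Bernoulli(expit(logit(0.0114) + ln 6.3·[c=1] +
  ln 2.43·[c=2])): the planted odds ratios and the reference-cluster
  baseline match the published estimates, so odds-ratio recovery is a
  genuine parameter-recovery experiment.
* **Determinism.** Every table and layer draws from its own stream split
  deterministically from the master seed (name-keyed `SeedSequence`), so
  identical configurations are byte-identical and adding a layer never
  perturbs other outputs.

What the synthetic study does *not* emulate: real coding depth (thousands
of SNOMED/ATC codes), informative missingness, care discontinuity, street
networks (intersections are a point layer, buffers are Euclidean), or
spatial autocorrelation beyond smooth gradients. Passing tests therefore
demonstrate algorithmic correctness and faithful parameter recovery under
the planted model — not that the clustering or the path model would find
the same structure in any particular real cohort.

## Problem sizes and numerical choices

Default problem sizes are chosen so the full validation suite runs on one
desk CPU: clustering recovery at n = 2,000 patients, odds-ratio recovery
at n = 50,000 over 50 replicates, oracle equivalence on hundreds of random
instances, calibration at 1,000 null replicates. Tolerances follow the
source of error: exact equality for combinatorial algorithms (LCS, SPADE,
VIF ordering), 1e-12 for closed-form entropy bounds, Monte-Carlo 3·SE for
geometric areas, and 15 % relative for stochastic parameter recovery.

Degenerate inputs are contracts, not surprises: two empty sequences have
no defined LCS distance (error); an empty buffer yields zero counts and
missing LUM; a 100 %-missing column cannot be imputed (error); perfect
separation in a logistic equation raises a named error rather than
returning a silent non-converged fit; an empty cluster yields an empty,
logged mining result.

## Known limitations

* The LCS normalization and linkage of the emulated analyses are not
  published; both are configuration choices here, and conclusions that
  depend on them should be checked under the alternatives.
* The mediator and outcome equations are fit equation-by-equation; this is
  exact for the recursive fully-observed system but does not provide
  latent-variable SEM fit indices, and no causal-mediation decomposition
  is attempted.
* MICE uses simple conditional draws (no predictive-mean matching, no
  posterior draws of coefficients), adequate for the MCAR missingness the
  generator plants.
* Buffer indicators are Euclidean; network-distance accessibility is out
  of scope.
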