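# Methods

This note documents the modelling choices behind forecasd: the procedure
and its assumptions, the parameters that matter, what the synthetic-data
generators do and do not emulate, the numerical decisions, and known
limitations.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The stacked ensemble

The score is a two-level stack of balanced random forests.  The central
assumptions are:

1. *Risk genes look alike* in developmental expression space (shared
   trajectory shapes across brain regions) and in interaction-network
   space (short mutual path distances), so a classifier trained on a small
   positive class generalizes genome-wide.
2. *The negative class can be approximated by random non-listed genes.*
   1,000 genes sampled uniformly outside the candidate database are
   treated as non-risk; some are surely mislabeled, which balanced
   per-tree sampling and the vote-fraction score tolerate.
3. *Stacking is safe only with out-of-bag level-1 scores.*  Training genes
   reach the level-2 model exclusively through predictions of trees whose
   bootstrap excluded them; otherwise the level-2 forest would learn to
   trust memorized level-1 outputs.

### Trajectory features

Per gene and region: replicate measurements at the same age are averaged
("averaging out" redundant timepoints); the (age, expression) points are
LOWESS-smoothed; the smoothed curve is linearly interpolated onto a shared
grid of `grid_size` (default 50) equally spaced post-conception-week
values spanning the global age range; grid points outside a region's
observed range take the nearest endpoint value (constant extension), since
regions differ in age coverage and interpolation alone would leave gaps.
The concatenated per-gene vector is z-scaled to mean 0, sd 1 (sample sd);
constant genes map to all zeros.

* Age scale: labels `<n> pcw|mos|yrs` map to post-conception weeks with
  birth = 40 pcw, 1 month = 52/12 weeks, 1 year = 52 weeks.  Any strictly
  monotone convention gives the same features up to grid placement; this
  one is fixed so results are reproducible.
* LOWESS span 2/3 with 3 robustness iterations — the classical defaults of
  the smoother family used.  Robustness iterations are skipped when the
  initial fit already interpolates the data exactly (residuals ≤ 1e-10 of
  scale): on exactly collinear input the robustness weights would be 0/0,
  and on such input the iterations are a no-op anyway.  With fewer than
  four distinct ages the averaged points are interpolated directly.
* Scaling orientation: "z-scale each timepoint for each gene" admits two
  readings.  The default scales each gene's concatenated 800-vector
  (making trajectories magnitude-free, so a gene's feature row is invariant
  to positive rescaling of its raw expression); per-timepoint column
  scaling is available via `scale="timepoint"`.
* One global grid rather than per-region grids, and deterministic column
  order (region lexicographic, then grid index), so feature matrices are
  byte-reproducible.

### Shortest-path features

Edges below confidence 0.4 are removed (a score of exactly 0.4 is kept);
distances are unweighted hop counts on the full node set.  Unreachable
pairs — including isolated nodes — are imputed with (max finite
off-diagonal distance) + 1: finite, and ordinally "farther than anything
observed".  A sentinel override is available.  Genes absent from the
network are simply not scored by the network model; they re-enter the
scored universe through meta-feature imputation if the expression model
covers them.

### Balanced forest engine

Each tree draws exactly `per_class` (default 70) positives and `per_class`
negatives *with replacement within class* (the stratified-bootstrap
convention; without-replacement is a switch), then grows an unpruned CART
tree with Gini impurity, `mtry = floor(sqrt(p))` candidate features per
split and minimum node size 1.  The per-tree in-bag multiset is stored,
enabling:

* exact OOB scores — a training row's score is the positive-vote fraction
  over trees whose in-bag excluded it (a row in-bag everywhere falls back
  to the all-trees score with a logged warning; with 1,000 trees the
  probability of that is negligible);
* split-usage counts — a feature "is used" if it appears in ≥ 1 internal
  node of ≥ 1 tree;
* backward elimination — fit, drop all zero-usage features, refit, until
  every retained feature is used.  Each round derives a fresh seed from
  (base seed, round index), so rounds are reproducible but not identical.
  The loop terminates in at most p rounds because the feature count
  strictly decreases until the exit round.

Elimination behavior is governed by the ratio of total split-usage draws
to the size of the feature pool: with many trees per feature nearly every
feature is touched at least once and nothing is eliminated, while at the
reference-like ratio of roughly 0.05 trees per feature the zero-usage tail
is substantial and noise features are purged over a handful of rounds.
Tests of the elimination property therefore size the forest to preserve
that ratio (30 trees for a 510-feature pool).

### Meta-features and the scored universe

The scored universe is every gene with at least one level-1 score (union
of the two sources).  Training positives are restricted to genes present
in *both* sources, and negatives are sampled from the same intersection,
so the two level-1 models and the level-2 model share one identical label
set.  The level-2 table has ten columns in fixed order (the two level-1
scores, DAWN, Krishnan, DAMAGES, and five TADA-based columns); each
missing value is imputed with the *training-set median* of its column and
flagged.  Median rather than mean: FDR-like columns are heavily
right-skewed.  Genes present only in the prior panel (no level-1 score)
are excluded from scoring.

A single top-level seed fans out deterministically to the label-sampling
and the three forest stages, so identical configuration yields a
byte-identical score table.

## Evaluation statistics

* **Decile assignment**: rank by score descending, ties broken by
  lexicographically smaller gene id; decile sizes differ by at most one;
  the same rank-based binning (at 5% width) drives the eQTL analysis.
* **Decile enrichment**: target classes count *distinct individuals*
  (recurrent LOF = LOF DNMs in ≥ 2 probands; singleton = exactly 1;
  recurrent missense analogous); a gene may belong to several classes.
  The baseline p₀ is the top-decile fraction of genes with ≥ 1 synonymous
  proband DNM, absorbing gene-length-driven mutation-rate differences.
  Genes with DNMs but no score are dropped from numerator and denominator
  (logged and reported).  The binomial upper tail is summed in log space.
* **Worked tail probability**: P(X ≥ 32 | n = 44, p₀ = 0.196) = 3.8e-14
  (the acceptance script recomputes it).  Recomputation from a baseline
  printed to three decimals can differ from a value computed from the
  unrounded baseline by a factor of ~1.3 at this magnitude, which is why
  agreement is asserted at order-of-magnitude precision.
* **Rank-sum test**: one-sided (subset greater).  Small tie-free pooled
  samples (n ≤ 25) use the exact permutation distribution — required for
  agreement with full enumeration on small instances — larger or tied
  samples the normal approximation with tie and continuity corrections.
  An all-tied input returns p = 1.
* **Fisher overlap**: exact two-sided p (probability-mass definition) with
  the conditional-MLE odds ratio as the primary estimate (the convention
  of the reference analysis environment) and the sample cross-product OR
  reported alongside (0 / inf / NaN on degenerate tables).
* **Covariate-adjusted benchmark**: ML logistic fit of candidate-set
  membership on [score + covariates] after removing excluded genes; the
  design is rejected if numerically collinear (condition number of the
  standardized design > 1e8) and separation is surfaced as an error rather
  than returned as a divergent coefficient.
* **eQTL/GWAS enrichment**: unit of counting is eQTL records; a record is
  a hit iff its GWAS p < 0.01; the headline Fisher test compares the top
  5% score bin to all lower bins; cumulative odds ratios are reported per
  bin boundary.

## Network clustering

Greedy agglomerative modularity optimization (the Clauset–Newman–Moore
scheme) on the induced subgraph of the genes of interest, with edge
confidences as weights (an unweighted switch exists) and *no* confidence
filter.  Clusters over `max_size` (200) are re-clustered depth-first on
their own induced subgraph; recursion stops when optimization returns a
single community, in which case the cluster is retained regardless of size
and prominently logged.  Clusters under `min_size` (30) are discarded with
a per-gene reason; isolated genes are discarded up front (modularity is
undefined without edges).  Vertices are inserted in lexicographic order so
identical inputs give identical clusterings.  Overlap statistics use an
upper-tail hypergeometric against a fixed background of 18,000 genes
regardless of how many genes were clustered; pLI enrichment tests
pLI > 0.5 membership per cluster against all other clustered genes.

## Synthetic-data generators

The generators produce inputs with the statistical structure the method
assumes, at a scale (defaults: 2,000 genes, 60 donors, 16 + 2 regions, 20
network communities, 76/1,000 labels) chosen so the full pipeline runs in
about a minute; the 76/120/1,000 positive/candidate/negative geometry
mirrors the reference study's label structure.

* **Expression**: donors get log-uniform ages from 8 pcw to 40 years; each
  adequate region samples ~32 donors with a 15% replicate rate; two
  regions are under-sampled to exercise the region filter.  Every gene has
  a smooth random background curve (polynomial + one Fourier harmonic of
  normalized log-age); risk genes add one of three trajectory archetypes
  (prenatal peak, postnatal rise, mid-development bump) with
  region-specific loadings and amplitude `expression_effect` (default 3,
  i.e. 3× the i.i.d. log-scale noise sd — the "signal-to-noise" quoted
  elsewhere is relative to that noise term, not to the background-curve
  variance).  With effect 0 the signal and background distributions
  coincide exactly, giving a proper null.  Values are exponentiated, so
  the matrix is positive and right-skewed like RPKM data.
* **Network**: planted partition over 20 communities; positives and
  candidates concentrate round-robin in the first 3; within/between edge
  probabilities 0.08/0.003; confidences uniform on [0.25, 1], so roughly a
  fifth of edges fall under the 0.4 filter.
* **Priors**: each column is `effect × signal + noise` (FDR-like columns
  are mapped through a normal survival function so nulls are uniform);
  per-column missingness defaults between 5% and 30% (DAMAGES 30%).
* **DNMs**: a lognormal length covariate multiplies all mutation rates;
  synonymous counts follow it alone (so the decile baseline has something
  to correct); LOF rates are multiplied by `lof_enrichment` (default 10)
  in positives — a multiplier of 1 is the null.  Mutations are assigned to
  5,000 probands across three cohort labels.
* **eQTL/GWAS**: ~4 records per gene; hit probability 0.3 for the top 5%
  of genes by the supplied score and 0.1 elsewhere; hits draw GWAS p
  uniformly below 0.01, non-hits above.
* **pLI**: Beta(4, 2) in risk communities, Beta(1.5, 4) elsewhere.

What the generators deliberately do **not** emulate: biological expression
dynamics (archetypes are geometric, not mechanistic), scale-free network
degree distributions, LD structure among GWAS p-values, cohort-specific
mutation calling, or correlated missingness across prior columns.  A green
test suite therefore demonstrates that the machinery is correct and
calibrated under the stated statistical structure, not that the method's
real-data performance claims transfer.

The permutation null used for the stacking check permutes the gene→label
assignment over the whole gene universe and evaluates against the permuted
assignment — the standard permutation-test construction.  Permuting labels
only within the fixed training set while evaluating against the true
labels is *not* a null here: the surviving handful of true positives among
the pseudo-positives, being clustered in feature space, still lifts the
whole risk-gene neighborhood.

## Problem sizes in tests

Unit tests run on reduced instances (hundreds of genes, tens-to-hundreds
of trees); the stacking checks run the full default study (2,000 genes,
1,000 trees, five seeds); calibration checks use 200 null replicates per
test; oracle-equivalence checks use 200 random instances per kernel.
These sizes were chosen so the whole suite completes in minutes while
keeping every statistical assertion comfortably powered.

## Known limitations

* Gene identifiers are matched exactly across sources; no alias or
  cross-reference resolution.
* The shortest-path feature matrix is dense (n² for n network genes);
  beyond ~2×10⁴ genes memory becomes the binding constraint.
* Backward elimination refits the full forest each round; with very large
  feature pools and many trees the first rounds dominate runtime.
* The conditional-MLE odds ratio is reported as NaN for doubly degenerate
  2×2 tables (a zero margin), where no MLE exists.
* Model archives are joblib pickles: readable only by a compatible
  scikit-learn, and not a long-term storage format.
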