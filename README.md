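# forecasd

Genome-wide prioritization of autism risk genes by a two-level stacked
ensemble of balanced random forests, together with the evaluation
statistics and network clustering used to interrogate the resulting score —
all exercisable end-to-end on synthetic data.

## Who this is for

Researchers ranking candidate disease genes from heterogeneous genome-scale
evidence: developmental brain expression, protein–protein interaction
topology, and previously published gene-level association scores.  The
package implements the full method as a library with a thin command-line
interface, plus generators that emulate every required input, so the whole
pipeline is testable without access to the original cohort downloads.

## The method

**Level 1.** Two balanced random forests are trained on a positive class of
established risk genes (SFARI 1/2-style; *n* = 76 in the reference
geometry) and 1,000 randomly sampled genes absent from the candidate
database:

* an **expression model** over trajectory features: per gene and brain
  region, expression is LOWESS-smoothed over post-conception age, linearly
  interpolated onto a shared 50-point grid, and z-scaled per gene — with 16
  regions surviving the ≥ 20-samples-per-region filter this yields
  16 × 50 = 800 features per gene;
* a **network model** over the gene × gene shortest-path (hop-count) matrix
  of the confidence-filtered interaction network (edges with score < 0.4
  removed; unreachable pairs imputed with max-finite + 1), with a
  backward-elimination loop that repeatedly drops features never selected
  by any tree.

Each of the 1,000 trees per forest is grown on exactly 70 positive and 70
negative in-bag draws (stratified bootstrap), and training genes are scored
**out-of-bag** — only by trees whose bootstrap excluded them.

**Level 2.** The two level-1 scores (OOB for training genes, so the stack
never sees a self-prediction) join eight prior gene-level scores (DAWN,
Krishnan, DAMAGES, and five TADA-based columns) as a 10-feature table for a
final balanced forest; its positive-vote fraction in [0, 1] is the
`forecASD` score.

**Evaluation.** Genes are ranked and split into deciles; a one-sided
binomial test asks whether genes with recurrent loss-of-function de novo
mutations (LOF DNMs in ≥ 2 probands) concentrate in the top decile, using
the top-decile proportion of genes with *synonymous* proband DNMs as the
expected baseline p₀ — correcting for gene-length-driven mutation-rate
differences.  Also included: a covariate-adjusted logistic benchmark (score
vs. held-out candidate-gene membership, controlling for the five TADA
columns), one-sided rank-sum tests, Fisher exact 2×2 overlap tests with
conditional-MLE odds ratios, and eQTL/GWAS enrichment over 5% score
quantiles.  Top-decile genes can be clustered on the unfiltered interaction
network by greedy modularity optimization with size constraints (> 200
re-clustered recursively, < 30 discarded) and per-cluster hypergeometric /
pLI-enrichment statistics.

## Worked example

`examples/01_train_stacked_ensemble.py` simulates a 500-gene study with
planted expression, network and prior signal, then trains the full stack:

```
scored genes:          500
training labels:       240
ensemble AUROC:        0.989
expression-only AUROC: 0.908
network-only AUROC:    0.833

level-2 feature importances (sum to 1):
BrainSpan_score                     0.254
STRING_score                        0.076
Krishnan                            0.134
...
```

The ensemble AUROC (0.989) matches or beats the better level-1 model
(0.908): stacking pools the trajectory, network and prior evidence per
gene without double-counting the training labels, because training genes
enter level 2 through their out-of-bag level-1 scores.

The other examples demonstrate the decile enrichment test
(`02_dnm_decile_enrichment.py`), eQTL/GWAS quantile enrichment
(`03_eqtl_gwas_enrichment.py`) and size-constrained network clustering
(`04_network_clusters.py`).

## Command line

```bash
forecasd --seed 7 simulate --out-dir inputs/            # synthetic study
forecasd --seed 7 train --input-dir inputs/ --out-dir run/
forecasd evaluate-dnm  --scores run/scores.tsv --dnm inputs/dnm.tsv  --out-dir run/dnm/
forecasd evaluate-eqtl --scores run/scores.tsv --eqtl inputs/eqtl.tsv --out-dir run/eqtl/
forecasd cluster --edges inputs/edges.tsv --scores run/scores.tsv --out-dir run/clusters/
```

Stage parameters come from an optional `--config config.yaml` with
per-stage blocks; every run writes a resolved-config copy and a log file
beside its outputs.  The score table has the fixed column order
`gene, BrainSpan_score, STRING_score, forecASD, is_training, oob`.

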