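"""Benchmark statistics for gene score tables.

The central comparison is mutation-rate-corrected decile enrichment: genes
are ranked by score and split into deciles, the expected top-decile
proportion is taken from genes carrying proband *synonymous* de novo
mutations (which absorbs gene-length-driven mutation-rate differences), and
a one-sided binomial tail tests whether genes in a target mutation class
(recurrent LOF, singleton LOF, recurrent missense) exceed it.

Also here: a covariate-adjusted logistic benchmark (score vs. membership in
a held-out candidate set, controlling for gene-level association
covariates), a one-sided rank-sum test, Fisher's exact 2x2 overlap test with
a conditional-MLE odds ratio, and the eQTL/GWAS quantile-bin enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact, hypergeom, mannwhitneyu
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio

from .errors import (
    CollinearityError,
    DegenerateInputError,
    SeparationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

TARGET_CLASSES = ("recurrent_LOF", "singleton_LOF", "recurrent_missense")


# ---------------------------------------------------------------------------
# Ranking helpers
# ---------------------------------------------------------------------------


def rank_genes(scores: pd.Series) -> pd.Index:
    """Genes ordered best-first: score descending, ties broken by
    lexicographically smaller gene id."""
    df = pd.DataFrame({"score": scores.to_numpy(float), "gene": scores.index.astype(str)})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Index(df["gene"].to_numpy(), name="gene")


def assign_quantile_bins(scores: pd.Series, n_bins: int) -> pd.Series:
    """Rank-based quantile bins, 1 = top scores; bin sizes differ by <= 1."""
    n = len(scores)
    if n < n_bins:
        raise ValidationError(f"need >= {n_bins} scored genes, got {n}")
    ordered = rank_genes(scores)
    ranks = np.arange(n)
    bins = (ranks * n_bins) // n + 1
    return pd.Series(bins, index=ordered, name="bin").reindex(scores.index.astype(str))


def assign_deciles(scores: pd.Series) -> pd.Series:
    """Per-gene decile index 1..10 (decile 1 = highest scores)."""
    return assign_quantile_bins(scores, 10)


# ---------------------------------------------------------------------------
# Binomial tail
# ---------------------------------------------------------------------------


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact one-sided binomial upper tail P(X >= k), X ~ Binomial(n, p0),
    summed in log space."""
    k, n = int(k), int(n)
    if not (0 <= k <= n):
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValidationError(f"p0 must lie in (0, 1), got {p0}")
    if k == 0:
        return 1.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1)
        - gammaln(i + 1)
        - gammaln(n - i + 1)
        + i * np.log(p0)
        + (n - i) * np.log1p(-p0)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


# ---------------------------------------------------------------------------
# Decile enrichment with synonymous baseline
# ---------------------------------------------------------------------------


@dataclass
class DecileEnrichment:
    """Result of a mutation-class decile-enrichment test."""

    target_class: str
    decile_fractions: np.ndarray  # fraction of target genes per decile, 10 values
    decile_counts: np.ndarray  # target genes per decile, sums to n
    k: int  # target genes in the top decile
    n: int  # scored target genes
    p0: float  # baseline (synonymous) top-decile proportion
    p_value: float
    n_dropped_unscored: int


def _genes_with_min_individuals(dnm: pd.DataFrame, consequence: str, at_least: int, exactly: bool = False) -> set[str]:
    sub = dnm[dnm["consequence"] == consequence]
    counts = sub.groupby("gene")["individual"].nunique()
    if exactly:
        return set(counts.index[counts == at_least])
    return set(counts.index[counts >= at_least])


def mutation_class_genes(dnm: pd.DataFrame, target_class: str) -> set[str]:
    """Gene set for a mutation class, counting distinct individuals."""
    if target_class == "recurrent_LOF":
        return _genes_with_min_individuals(dnm, "LOF", 2)
    if target_class == "singleton_LOF":
        return _genes_with_min_individuals(dnm, "LOF", 1, exactly=True)
    if target_class == "recurrent_missense":
        return _genes_with_min_individuals(dnm, "missense", 2)
    raise ValidationError(f"unknown target class {target_class!r}")


def decile_enrichment_test(
    scores: pd.Series, dnm: pd.DataFrame, target_class: str = "recurrent_LOF"
) -> DecileEnrichment:
    """Test for over-representation of a mutation class in the top score
    decile, with the synonymous-mutation top-decile proportion as baseline.

    Genes carrying DNMs but absent from the score table are excluded from
    both numerator and denominator (the count is logged and reported).
    """
    scored = set(scores.index.astype(str))
    target = mutation_class_genes(dnm, target_class)
    baseline = _genes_with_min_individuals(dnm, "synonymous", 1)
    n_dropped = len((target | baseline) - scored)
    if n_dropped:
        logger.info("%d DNM gene(s) lack scores and are excluded", n_dropped)
    target &= scored
    baseline &= scored
    if not target:
        raise DegenerateInputError(f"no scored gene in target class {target_class!r}")
    if not baseline:
        raise DegenerateInputError("no scored gene carries a synonymous DNM")

    deciles = assign_deciles(scores)
    p0 = float((deciles.loc[sorted(baseline)] == 1).mean())
    if not (0.0 < p0 < 1.0):
        raise DegenerateInputError(
            f"degenerate synonymous baseline proportion p0={p0} "
            "(all or none of the baseline genes in the top decile)"
        )
    target_deciles = deciles.loc[sorted(target)]
    counts = np.array([(target_deciles == d).sum() for d in range(1, 11)])
    n = int(counts.sum())
    k = int(counts[0])
    return DecileEnrichment(
        target_class=target_class,
        decile_fractions=counts / n,
        decile_counts=counts,
        k=k,
        n=n,
        p0=p0,
        p_value=binomial_tail(k, n, p0),
        n_dropped_unscored=n_dropped,
    )


# ---------------------------------------------------------------------------
# Covariate-adjusted logistic benchmark
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    z: float
    p_value: float
    coefficient: float
    n: int
    n_positive: int


def covariate_adjusted_association(
    score: pd.Series,
    covariates: pd.DataFrame,
    positive_set: set[str],
    excluded: set[str] = frozenset(),
) -> AssociationResult:
    """Wald test of a score's association with membership in ``positive_set``
    after adjusting for gene-level covariates.

    Fits a maximum-likelihood logistic regression of membership on
    [intercept, score, covariates] over genes present in both inputs, after
    removing ``excluded`` genes; returns the score coefficient with its Wald
    Z and two-sided p.
    """
    genes = score.index.intersection(covariates.index).astype(str)
    genes = pd.Index([g for g in genes if g not in excluded])
    if len(genes) == 0:
        raise DegenerateInputError("no gene left after exclusion/intersection")
    y = np.array([1 if g in positive_set else 0 for g in genes])
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateInputError("positive set and complement must both be non-empty")

    X = pd.concat([score.reindex(genes).rename("score"), covariates.reindex(genes)], axis=1)
    Xv = X.to_numpy(float)
    if not np.all(np.isfinite(Xv)):
        raise ValidationError("score/covariate matrix contains non-finite values")
    # condition check on standardized columns so scale does not mask collinearity
    sd = Xv.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise CollinearityError("a constant column cannot enter the logistic fit")
    Z = (Xv - Xv.mean(axis=0)) / sd
    cond = np.linalg.cond(Z)
    if cond > 1e8:
        raise CollinearityError(f"design matrix numerically collinear (cond={cond:.2e})")

    design = sm.add_constant(Xv, prepend=True)
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError subclasses
        if "erfect" in type(exc).__name__ or "separation" in str(exc).lower():
            raise SeparationError(str(exc)) from exc
        raise
    if not fit.mle_retvals.get("converged", True) and np.max(np.abs(fit.params)) > 50:
        raise SeparationError("logistic fit did not converge (likely separation)")
    return AssociationResult(
        z=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        coefficient=float(fit.params[1]),
        n=len(y),
        n_positive=int(y.sum()),
    )


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------


def ranksum_test(scores: pd.Series, subset: set[str]) -> float:
    """One-sided (subset greater) two-sample rank-sum p-value of the subset's
    scores against all other scored genes.

    Small tie-free samples (pooled n <= 25) use the exact permutation
    distribution; larger or tied samples use the normal approximation with
    tie and continuity corrections.  If every score is identical the test is
    maximally non-informative and returns 1.
    """
    idx = scores.index.astype(str)
    in_sub = idx.isin(subset)
    x = scores.to_numpy(float)[in_sub]
    y = scores.to_numpy(float)[~in_sub]
    if len(x) == 0 or len(y) == 0:
        raise DegenerateInputError("subset and complement must both be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and len(pooled) <= 25) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Fisher overlap
# ---------------------------------------------------------------------------


@dataclass
class FisherResult:
    odds_ratio: float  # conditional maximum-likelihood estimate
    p_value: float  # exact two-sided
    table: np.ndarray  # 2x2 [[a, b], [c, d]]
    sample_odds_ratio: float  # cross-product ad/bc


def _fisher_from_table(table: np.ndarray) -> FisherResult:
    table = np.asarray(table, dtype=np.int64)
    _, p = fisher_exact(table, alternative="two-sided")
    a, b = table[0]
    c, d = table[1]
    # cross-product convention: 0 when the numerator vanishes, inf when only
    # the denominator does, nan for the doubly degenerate table
    if a * d == 0 and b * c == 0:
        sample_or = np.nan
    elif a * d == 0:
        sample_or = 0.0
    elif b * c == 0:
        sample_or = np.inf
    else:
        sample_or = (a * d) / (b * c)
    try:
        cond_or = float(_conditional_odds_ratio(table, kind="conditional").statistic)
    except Exception:
        cond_or = np.nan
    return FisherResult(
        odds_ratio=cond_or,
        p_value=float(p),
        table=table,
        sample_odds_ratio=float(sample_or) if np.isfinite(sample_or) else sample_or,
    )


def fisher_overlap(setA: set[str], setB: set[str], background) -> FisherResult:
    """Fisher's exact test of overlap between two gene sets.

    ``background`` is either the gene universe (a set containing A and B) or
    its integer size.  Reports the conditional-MLE odds ratio as primary and
    the sample cross-product odds ratio alongside.
    """
    setA, setB = set(setA), set(setB)
    if isinstance(background, (int, np.integer)):
        bg = int(background)
        if bg < len(setA | setB):
            raise ValidationError("background smaller than |A union B|")
    else:
        bg_set = set(background)
        if not (setA <= bg_set and setB <= bg_set):
            raise ValidationError("setA and setB must be subsets of the background")
        bg = len(bg_set)
    a = len(setA & setB)
    b = len(setA - setB)
    c = len(setB - setA)
    d = bg - a - b - c
    return _fisher_from_table(np.array([[a, b], [c, d]]))


# ---------------------------------------------------------------------------
# eQTL / GWAS enrichment
# ---------------------------------------------------------------------------


@dataclass
class EqtlGwasEnrichment:
    top_bin: FisherResult
    cumulative: pd.DataFrame  # columns: bin, odds_ratio, p_value (len n_bins - 1)
    n_bins: int
    n_records: int
    n_dropped_unscored: int


def eqtl_gwas_enrichment(
    scores: pd.Series,
    eqtl: pd.DataFrame,
    bin_width: float = 0.05,
    gwas_cut: float = 0.01,
) -> EqtlGwasEnrichment:
    """Quantile-bin enrichment of GWAS-supported eQTL among high-scoring genes.

    Genes are split into ``1/bin_width`` rank-based score quantile bins (bin
    1 = top).  Each eQTL record is a hit iff its GWAS p < ``gwas_cut``; the
    unit of counting is eQTL records.  The headline test compares the top bin
    against all lower bins with Fisher's exact test; for each bin boundary
    the cumulative odds ratio (that bin and every better bin vs. all lower
    bins) is reported as well.
    """
    if not (0.0 < bin_width <= 0.5):
        raise ValidationError("bin_width must lie in (0, 0.5]")
    n_bins = int(round(1.0 / bin_width))
    recs = eqtl.copy()
    recs["gene"] = recs["gene"].astype(str)
    scored = set(scores.index.astype(str))
    keep = recs["gene"].isin(scored)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%d eQTL record(s) reference unscored genes and are dropped", n_dropped)
    recs = recs[keep]
    if len(recs) == 0:
        raise DegenerateInputError("no eQTL record maps to a scored gene")

    bins = assign_quantile_bins(scores, n_bins)
    recs = recs.assign(
        bin=bins.reindex(recs["gene"]).to_numpy(),
        hit=recs["gwas_p"].to_numpy(float) < gwas_cut,
    )
    total_hits = int(recs["hit"].sum())
    if total_hits == 0 or total_hits == len(recs):
        raise DegenerateInputError("all or none of the eQTL records are GWAS hits")

    hit_by_bin = recs.groupby("bin")["hit"].sum().reindex(range(1, n_bins + 1), fill_value=0)
    n_by_bin = recs.groupby("bin").size().reindex(range(1, n_bins + 1), fill_value=0)

    rows = []
    top_result = None
    for b in range(1, n_bins):
        hi_hits = int(hit_by_bin.loc[:b].sum())
        hi_n = int(n_by_bin.loc[:b].sum())
        lo_hits = total_hits - hi_hits
        lo_n = int(n_by_bin.sum()) - hi_n
        table = np.array(
            [[hi_hits, hi_n - hi_hits], [lo_hits, lo_n - lo_hits]], dtype=np.int64
        )
        res = _fisher_from_table(table)
        if b == 1:
            top_result = res
        rows.append({"bin": b, "odds_ratio": res.odds_ratio, "p_value": res.p_value})

    return EqtlGwasEnrichment(
        top_bin=top_result,
        cumulative=pd.DataFrame(rows),
        n_bins=n_bins,
        n_records=len(recs),
        n_dropped_unscored=n_dropped,
    )
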