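"""Benchmark statistics against brute-force and enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import forecasd as f
from forecasd.errors import (
    CollinearityError,
    DegenerateInputError,
    ValidationError,
)
from forecasd.evaluation import mutation_class_genes


def series(values, prefix="g"):
    return pd.Series(
        values, index=pd.Index([f"{prefix}{i:04d}" for i in range(len(values))], name="gene")
    )


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def binomial_tail_oracle(k, n, p0):
    """Direct term-by-term summation with exact binomial coefficients."""
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
    return total


def hypergeom_tail_oracle(overlap, background, n_ref, n_draw):
    """P(X >= overlap) by summation of exact hypergeometric terms."""
    total = 0.0
    for x in range(overlap, min(n_ref, n_draw) + 1):
        total += (
            math.comb(n_ref, x)
            * math.comb(background - n_ref, n_draw - x)
            / math.comb(background, n_draw)
        )
    return total


def fisher_oracle(table):
    """Two-sided exact p by full enumeration over the fixed-margin family,
    and the conditional-MLE odds ratio from the noncentral likelihood."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)

    def log_hyper(x):
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1) - math.lgamma(r2 - c1 + x + 1)
            - (math.lgamma(r1 + r2 + 1) - math.lgamma(c1 + 1) - math.lgamma(r1 + r2 - c1 + 1))
        )

    probs = {x: math.exp(log_hyper(x)) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    p_two = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))

    # conditional MLE: solve E_psi[X] = a for the noncentral hypergeometric
    def mean_at(log_psi):
        logs = {x: log_hyper(x) + x * log_psi for x in probs}
        m = max(logs.values())
        ws = {x: math.exp(v - m) for x, v in logs.items()}
        z = sum(ws.values())
        return sum(x * w for x, w in ws.items()) / z

    if a == hi:
        or_mle = math.inf
    elif a == lo:
        or_mle = 0.0
    else:
        lo_b, hi_b = -50.0, 50.0
        for _ in range(200):
            mid = 0.5 * (lo_b + hi_b)
            if mean_at(mid) < a:
                lo_b = mid
            else:
                hi_b = mid
        or_mle = math.exp(0.5 * (lo_b + hi_b))
    return or_mle, p_two


def ranksum_enumeration_oracle(x, y):
    """Exact one-sided (x greater) rank-sum p by enumerating all subsets."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[: len(x)].sum()
    n, k = len(pooled), len(x)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), k):
        total += 1
        if ranks[list(combo)].sum() >= observed - 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Deciles
# ---------------------------------------------------------------------------


class TestAssignDeciles:
    def test_equal_sizes(self):
        deciles = f.assign_deciles(series(np.arange(20.0)))
        assert deciles.value_counts().eq(2).all()

    def test_top_scores_get_decile_one(self):
        s = series(np.arange(20.0))
        deciles = f.assign_deciles(s)
        top2 = s.nlargest(2).index
        assert (deciles.loc[top2] == 1).all()

    def test_ties_break_lexicographically(self):
        s = pd.Series([1.0] * 10, index=[f"g{i}" for i in range(10)])
        s.iloc[3:] = 0.5
        s.iloc[:3] = 1.0
        # g0..g2 at 1.0; all others tied at 0.5 -> g3 fills decile 1's last slot? n=10 -> one per decile
        deciles = f.assign_deciles(s)
        assert deciles["g0"] == 1 and deciles["g1"] == 2 and deciles["g2"] == 3
        assert deciles["g3"] == 4  # lexicographically smallest of the tied block

    def test_reversed_scores_reverse_assignment(self):
        s = series(np.arange(30.0))
        d1 = f.assign_deciles(s)
        d2 = f.assign_deciles(-s)
        assert (d1 + d2 == 11).all()

    def test_fewer_than_ten_genes_raises(self):
        with pytest.raises(ValidationError):
            f.assign_deciles(series(np.arange(9.0)))

    def test_counts_partition(self):
        s = series(np.random.default_rng(1).normal(size=103))
        deciles = f.assign_deciles(s)
        sizes = deciles.value_counts()
        assert sizes.sum() == 103
        assert sizes.max() - sizes.min() <= 1


# ---------------------------------------------------------------------------
# Binomial tail
# ---------------------------------------------------------------------------


class TestBinomialTail:
    def test_zero_successes_is_one(self):
        assert f.binomial_tail(0, 25, 0.3) == 1.0

    def test_fair_coin_symmetry(self):
        assert f.binomial_tail(3, 5, 0.5) == pytest.approx(0.5, rel=1e-12)

    def test_against_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 31))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.02, 0.98))
            if k == 0:
                continue
            expected = binomial_tail_oracle(k, n, p0)
            assert f.binomial_tail(k, n, p0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_k(self):
        vals = [f.binomial_tail(k, 40, 0.2) for k in range(41)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValidationError):
            f.binomial_tail(5, 4, 0.2)
        with pytest.raises(ValidationError):
            f.binomial_tail(1, 4, 0.0)


# ---------------------------------------------------------------------------
# Decile enrichment
# ---------------------------------------------------------------------------


def dnm_from_sets(lof_recurrent=(), lof_single=(), missense_recurrent=(), synonymous=()):
    rows = []
    for g in lof_recurrent:
        rows += [(g, "p1", "MSSNG", "LOF"), (g, "p2", "SPARK", "LOF")]
    for g in lof_single:
        rows.append((g, "p3", "ASC", "LOF"))
    for g in missense_recurrent:
        rows += [(g, "p4", "MSSNG", "missense"), (g, "p5", "ASC", "missense")]
    for g in synonymous:
        rows.append((g, "p6", "SPARK", "synonymous"))
    return pd.DataFrame(rows, columns=["gene", "individual", "cohort", "consequence"])


class TestDecileEnrichment:
    def test_mutation_classes_count_distinct_individuals(self):
        dnm = dnm_from_sets(lof_recurrent=["gA"], lof_single=["gB"])
        # same individual twice in one gene stays a singleton
        dnm = pd.concat(
            [dnm, pd.DataFrame([("gB", "p3", "ASC", "LOF")], columns=dnm.columns)]
        )
        assert mutation_class_genes(dnm, "recurrent_LOF") == {"gA"}
        assert mutation_class_genes(dnm, "singleton_LOF") == {"gB"}

    def test_all_targets_in_top_decile_closed_form(self):
        scores = series(np.arange(100.0))
        top = [f"g{i:04d}" for i in (99, 98, 97)]  # top decile genes
        baseline = [f"g{i:04d}" for i in range(0, 100, 10)]  # one per decile
        dnm = dnm_from_sets(lof_recurrent=top, synonymous=baseline)
        res = f.decile_enrichment_test(scores, dnm, "recurrent_LOF")
        assert res.n == 3 and res.k == 3
        assert res.p0 == pytest.approx(0.1)
        assert res.p_value == pytest.approx(res.p0**3, rel=1e-9)
        assert res.decile_counts.sum() == res.n

    def test_unscored_dnm_genes_dropped(self):
        scores = series(np.arange(50.0))
        dnm = dnm_from_sets(lof_recurrent=["g0049", "zz_not_scored"], synonymous=["g0000", "g0048"])
        res = f.decile_enrichment_test(scores, dnm, "recurrent_LOF")
        assert res.n == 1
        assert res.n_dropped_unscored == 1

    def test_empty_target_class_raises(self):
        scores = series(np.arange(20.0))
        dnm = dnm_from_sets(synonymous=["g0000", "g0019"])
        with pytest.raises(DegenerateInputError):
            f.decile_enrichment_test(scores, dnm, "recurrent_LOF")


# ---------------------------------------------------------------------------
# Covariate-adjusted association
# ---------------------------------------------------------------------------


def logistic_benchmark_data(rng, n=5000, beta_score=1.0, n_cov=5):
    cov = rng.normal(size=(n, n_cov))
    score = rng.normal(size=n) + 0.5 * cov[:, 0]
    logit = -2.0 + beta_score * score + cov @ np.full(n_cov, 0.4)
    p = 1 / (1 + np.exp(-logit))
    y = rng.random(n) < p
    idx = pd.Index([f"g{i:05d}" for i in range(n)], name="gene")
    return (
        pd.Series(score, index=idx),
        pd.DataFrame(cov, index=idx, columns=[f"c{j}" for j in range(n_cov)]),
        {g for g, yy in zip(idx, y) if yy},
    )


class TestCovariateAdjustedAssociation:
    def test_power_with_true_conditional_effect(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            score, cov, pos = logistic_benchmark_data(rng, beta_score=1.0)
            res = f.covariate_adjusted_association(score, cov, pos)
            if res.z > 0 and res.p_value < 0.05:
                hits += 1
        assert hits >= 90

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(43)
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            score, cov, pos = logistic_benchmark_data(rng, n=2000, beta_score=0.0)
            res = f.covariate_adjusted_association(score, cov, pos)
            if abs(res.z) > 1.96:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.08

    def test_duplicated_covariate_raises_collinearity(self):
        rng = np.random.default_rng(44)
        score, cov, pos = logistic_benchmark_data(rng, n=500)
        cov["dup"] = score
        with pytest.raises(CollinearityError):
            f.covariate_adjusted_association(score, cov, pos)

    def test_excluded_genes_removed(self):
        rng = np.random.default_rng(45)
        score, cov, pos = logistic_benchmark_data(rng, n=1000)
        excluded = set(list(pos)[:10])
        res = f.covariate_adjusted_association(score, cov, pos, excluded=excluded)
        assert res.n == 1000 - 10


# ---------------------------------------------------------------------------
# Rank-sum
# ---------------------------------------------------------------------------


class TestRanksum:
    @pytest.mark.parametrize("n,k", [(8, 3), (10, 4), (12, 5)])
    def test_extreme_subset_matches_enumeration_minimum(self, n, k):
        scores = series(np.arange(float(n)))
        subset = set(scores.nlargest(k).index)
        p = f.ranksum_test(scores, subset)
        assert p == pytest.approx(1.0 / math.comb(n, k), rel=1e-9)

    def test_matches_enumeration_on_random_small_samples(self):
        rng = np.random.default_rng(9)
        for _ in range(20)  :
            n = int(rng.integers(6, 13))
            k = int(rng.integers(2, n - 1))
            vals = rng.permutation(np.arange(float(n)))  # distinct, tie-free
            scores = series(vals)
            subset = set(rng.choice(scores.index, size=k, replace=False))
            p = f.ranksum_test(scores, subset)
            expected = ranksum_enumeration_oracle(
                scores[scores.index.isin(subset)].to_numpy(),
                scores[~scores.index.isin(subset)].to_numpy(),
            )
            assert p == pytest.approx(expected, rel=1e-9)

    def test_all_tied_returns_one(self):
        scores = series(np.ones(30))
        assert f.ranksum_test(scores, set(scores.index[:10])) == 1.0

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(500):
            scores = series(rng.normal(size=100))
            subset = set(rng.choice(scores.index, size=20, replace=False))
            ps.append(f.ranksum_test(scores, subset))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_empty_side_raises(self):
        scores = series(np.arange(10.0))
        with pytest.raises(DegenerateInputError):
            f.ranksum_test(scores, set(scores.index))


# ---------------------------------------------------------------------------
# Fisher overlap
# ---------------------------------------------------------------------------


class TestFisherOverlap:
    def test_matches_enumeration_oracle(self):
        genes = [f"g{i}" for i in range(100)]
        setA, setB = set(genes[:10]), set(genes[5:25])
        res = f.fisher_overlap(setA, setB, set(genes))
        or_exp, p_exp = fisher_oracle(res.table)
        assert res.p_value == pytest.approx(p_exp, rel=1e-12)
        assert res.odds_ratio == pytest.approx(or_exp, rel=1e-6)

    def test_random_tables_match_oracle(self):
        from forecasd.evaluation import _fisher_from_table

        rng = np.random.default_rng(11)
        for _ in range(200):
            table = rng.integers(0, 26, size=(2, 2))
            res = _fisher_from_table(table)
            or_exp, p_exp = fisher_oracle(table)
            assert res.p_value == pytest.approx(p_exp, rel=1e-12)
            if np.isfinite(or_exp) and or_exp > 0:
                assert res.odds_ratio == pytest.approx(or_exp, rel=1e-6)

    def test_disjoint_sets_sample_or_zero(self):
        genes = [f"g{i}" for i in range(50)]
        res = f.fisher_overlap(set(genes[:5]), set(genes[5:15]), set(genes))
        assert res.sample_odds_ratio == 0.0

    def test_degenerate_subset_of_background_equals_one(self):
        genes = [f"g{i}" for i in range(30)]
        res = f.fisher_overlap(set(genes[:8]), set(genes), set(genes))
        assert res.p_value == pytest.approx(1.0)

    def test_swapping_sets_preserves_p_and_or(self):
        genes = [f"g{i}" for i in range(80)]
        A, B = set(genes[:15]), set(genes[10:40])
        r1 = f.fisher_overlap(A, B, set(genes))
        r2 = f.fisher_overlap(B, A, set(genes))
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-9)

    def test_background_smaller_than_union_raises(self):
        with pytest.raises(ValidationError):
            f.fisher_overlap({"a", "b"}, {"c"}, 2)


# ---------------------------------------------------------------------------
# eQTL / GWAS enrichment
# ---------------------------------------------------------------------------


def make_eqtl(rng, scores, hit_prob_top, hit_prob_rest, per_gene=5, top_frac=0.05):
    order = scores.sort_values(ascending=False)
    n_top = int(round(top_frac * len(scores)))
    top = set(order.index[:n_top])
    rows = []
    i = 0
    for gene, _ in scores.items():
        for _ in range(rng.poisson(per_gene)):
            p_hit = hit_prob_top if gene in top else hit_prob_rest
            hit = rng.random() < p_hit
            gp = rng.uniform(0, 0.01) if hit else rng.uniform(0.01, 1)
            rows.append((f"rs{i}", gene, max(gp, 1e-12)))
            i += 1
    return pd.DataFrame(rows, columns=["snp", "gene", "gwas_p"])


class TestEqtlGwasEnrichment:
    def test_cumulative_vector_length(self):
        rng = np.random.default_rng(12)
        scores = series(rng.normal(size=200))
        eqtl = make_eqtl(rng, scores, 0.3, 0.1)
        res = f.eqtl_gwas_enrichment(scores, eqtl)
        assert len(res.cumulative) == res.n_bins - 1

    def test_signal_detected(self):
        rng = np.random.default_rng(13)
        scores = series(rng.normal(size=2000))
        eqtl = make_eqtl(rng, scores, 0.3, 0.1)
        res = f.eqtl_gwas_enrichment(scores, eqtl)
        assert res.top_bin.odds_ratio > 2.0
        assert res.top_bin.p_value < 1e-10

    def test_records_for_unscored_genes_dropped(self):
        rng = np.random.default_rng(14)
        scores = series(rng.normal(size=100))
        eqtl = make_eqtl(rng, scores, 0.2, 0.1)
        eqtl.loc[0, "gene"] = "zz_unknown"
        res = f.eqtl_gwas_enrichment(scores, eqtl)
        assert res.n_dropped_unscored == 1

    def test_degenerate_all_hits_raises(self):
        rng = np.random.default_rng(15)
        scores = series(rng.normal(size=100))
        eqtl = make_eqtl(rng, scores, 1.0, 1.0)
        with pytest.raises(DegenerateInputError):
            f.eqtl_gwas_enrichment(scores, eqtl)
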