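"""Synthetic study generators.

Produces every input the pipeline consumes — expression bundle, interaction
network, prior-score panel, positive/exclusion gene lists, DNM table,
eQTL/GWAS table and pLI values — with the statistical structure the method
assumes, so each stage is testable without any external download:

* expression: irregular donor ages with replicate measurements, a few
  under-sampled regions (to exercise the region filter), and risk genes
  drawn from a small set of smooth developmental trajectory archetypes;
* network: planted-partition topology in which risk genes concentrate in a
  minority of communities, with edge confidences straddling the 0.4 filter;
* evaluation panel: priors correlated with the true labels (with per-column
  missingness), DNMs whose synonymous baseline follows a gene-length
  covariate while loss-of-function mutations are enriched in risk genes,
  eQTL whose GWAS hit probability rises with gene score, and pLI elevated in
  the risk-gene communities.

Everything is deterministic given the config seed; each generator derives
its own stream so the pieces can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .errors import ValidationError
from .io import ExpressionBundle, InteractionNetwork
from .pipeline import META_COLUMNS

PRIOR_COLUMNS = META_COLUMNS[2:]

_DEF_MISSINGNESS = {
    "DAWN": 0.2,
    "Krishnan": 0.1,
    "DAMAGES": 0.3,
    "TADA_BF": 0.15,
    "tadaFdrAscSscExomeSscAgpSmallDel": 0.05,
    "tadaFdrAscSscExome": 0.05,
    "tadaFdrAscExome": 0.05,
    "tadaFdrSscExome": 0.05,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the geometry of the reference study where it states one
    (76 positives, 1,000 negatives, 16 adequately sampled regions, a 0.4
    confidence filter, 10x recurrent-LOF enrichment in risk genes) and are
    otherwise sized so the full pipeline runs in minutes (2,000 genes, 60
    donors, 20 network communities).
    """

    seed: int
    n_genes: int = 2000
    # expression
    n_regions: int = 16  # regions meeting the sample threshold
    n_underpowered_regions: int = 2  # regions below it, dropped by the filter
    samples_per_region: int = 32
    underpowered_samples: int = 8
    n_donors: int = 60
    replicate_rate: float = 0.15
    expression_effect: float = 3.0  # archetype amplitude (log scale) = SNR vs noise_sd
    background_amplitude: float = 1.0
    noise_sd: float = 1.0
    # labels
    n_positive: int = 76
    n_candidate: int = 120  # lower-confidence genes: excluded from negatives
    n_negative: int = 1000
    candidate_effect: float = 0.6  # candidate signal relative to positives
    # network
    n_communities: int = 20
    n_positive_communities: int = 3
    p_within: float = 0.08
    p_between: float = 0.003
    conf_low: float = 0.25
    conf_high: float = 1.0
    # priors
    prior_effect: float = 1.5
    prior_missingness: dict = field(default_factory=lambda: dict(_DEF_MISSINGNESS))
    # DNM
    n_probands: int = 5000
    syn_rate: float = 0.5  # mean synonymous DNMs per gene
    lof_rate: float = 0.1  # mean LOF DNMs per unenriched gene
    missense_rate: float = 0.15
    lof_enrichment: float = 10.0  # rate multiplier in positives (1.0 = null)
    missense_enrichment: float = 4.0
    length_sd: float = 0.6  # lognormal sd of the gene-length covariate
    # eQTL / GWAS
    eqtl_per_gene: float = 4.0
    eqtl_hit_high: float = 0.3
    eqtl_hit_low: float = 0.1
    eqtl_top_fraction: float = 0.05
    gwas_cut: float = 0.01
    # pLI
    pli_high: tuple[float, float] = (4.0, 2.0)  # Beta(a, b) in risk communities
    pli_low: tuple[float, float] = (1.5, 4.0)

    def validate(self) -> None:
        probs = [
            self.replicate_rate,
            self.p_within,
            self.p_between,
            self.conf_low,
            self.conf_high,
            self.eqtl_hit_high,
            self.eqtl_hit_low,
            self.eqtl_top_fraction,
            self.gwas_cut,
            *self.prior_missingness.values(),
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        counts = [
            self.n_genes,
            self.n_regions,
            self.samples_per_region,
            self.n_donors,
            self.n_positive,
            self.n_negative,
            self.n_probands,
            self.n_communities,
            self.n_positive_communities,
        ]
        if not all(c > 0 for c in counts):
            raise ValidationError("all counts must be positive")
        if self.n_positive + self.n_candidate >= self.n_genes:
            raise ValidationError("n_positive + n_candidate must be < n_genes")
        if self.n_positive_communities > self.n_communities:
            raise ValidationError("n_positive_communities exceeds n_communities")
        if self.conf_low > self.conf_high:
            raise ValidationError("conf_low must not exceed conf_high")
        if self.lof_enrichment < 0 or self.missense_enrichment < 0:
            raise ValidationError("enrichment multipliers must be >= 0")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), stream)))


def gene_ids(config: SimulationConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


def make_labels(config: SimulationConfig) -> pd.DataFrame:
    """True gene roles: the first ``n_positive`` ids are established risk
    genes, the next ``n_candidate`` are lower-confidence candidates (kept out
    of the negative pool, like database-listed genes of any score)."""
    genes = gene_ids(config)
    labels = pd.DataFrame(index=pd.Index(genes, name="gene"))
    labels["is_positive"] = False
    labels["is_candidate"] = False
    labels.iloc[: config.n_positive, 0] = True
    labels.iloc[config.n_positive : config.n_positive + config.n_candidate, 1] = True
    return labels


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

_AGE_MIN, _AGE_MAX = 8.0, 2120.0  # 8 pcw .. 40 yrs


def _archetypes(u: np.ndarray) -> np.ndarray:
    """Three smooth developmental trajectory archetypes on normalized
    log-age u in [0, 1]: prenatal peak, postnatal rise, mid-development bump."""
    early = np.exp(-(((u - 0.15) / 0.18) ** 2))
    late = 1.0 / (1.0 + np.exp(-(u - 0.6) * 8.0))
    mid = np.exp(-(((u - 0.5) / 0.15) ** 2))
    return np.stack([early, late, mid])


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionBundle, pd.DataFrame]:
    """Generate the expression bundle and return it with the true labels.

    Signal genes (positives; candidates at ``candidate_effect`` strength) add
    an archetype trajectory with region-specific amplitude on top of each
    gene's smooth random background curve; with ``expression_effect=0`` the
    signal and background distributions coincide (a proper null).
    """
    config.validate()
    rng = _rng(config, 1)
    genes = gene_ids(config)
    labels = make_labels(config)

    donors = [f"D{i:03d}" for i in range(config.n_donors)]
    donor_age = np.exp(rng.uniform(np.log(_AGE_MIN), np.log(_AGE_MAX), size=config.n_donors))

    region_names = [f"R{i + 1:02d}" for i in range(config.n_regions)] + [
        f"U{i + 1:02d}" for i in range(config.n_underpowered_regions)
    ]
    rows = []
    for r, region in enumerate(region_names):
        n_r = (
            config.samples_per_region
            if r < config.n_regions
            else config.underpowered_samples
        )
        n_r = min(n_r, config.n_donors)
        chosen = rng.choice(config.n_donors, size=n_r, replace=False)
        for d in chosen:
            rows.append((donors[d], region, donor_age[d]))
            if rng.random() < config.replicate_rate:  # replicate measurement
                rows.append((donors[d], region, donor_age[d]))
    meta = pd.DataFrame(rows, columns=["donor", "region", "age_pcw"])
    meta.index = pd.Index([f"S{i + 1:04d}" for i in range(len(meta))], name="sample")

    u = (np.log(meta["age_pcw"].to_numpy()) - np.log(_AGE_MIN)) / (
        np.log(_AGE_MAX) - np.log(_AGE_MIN)
    )
    arch = _archetypes(u)  # (3, n_samples)

    n_genes, n_samples = config.n_genes, len(meta)
    # smooth random background curve per gene (same distribution for all genes)
    basis = np.stack(
        [np.ones_like(u), u, u**2, np.sin(2 * np.pi * u), np.cos(2 * np.pi * u)]
    )
    coefs = rng.normal(0.0, config.background_amplitude / 2.0, size=(n_genes, basis.shape[0]))
    base_level = rng.normal(2.0, 1.0, size=n_genes)

    signal_strength = np.where(
        labels["is_positive"], 1.0, np.where(labels["is_candidate"], config.candidate_effect, 0.0)
    )
    archetype_of_gene = np.arange(n_genes) % 3
    region_codes = meta["region"].map({r: i for i, r in enumerate(region_names)}).to_numpy()
    loadings = rng.uniform(0.5, 1.5, size=(n_genes, len(region_names)))

    log_expr = (
        base_level[:, None]
        + coefs @ basis
        + config.expression_effect
        * signal_strength[:, None]
        * loadings[:, region_codes]
        * arch[archetype_of_gene, :]
        + rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
    )
    values = pd.DataFrame(
        np.exp(log_expr), index=pd.Index(genes, name="gene"), columns=meta.index
    )
    return ExpressionBundle(values=values, sample_meta=meta), labels


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


def simulate_network(
    config: SimulationConfig, labels: pd.DataFrame
) -> tuple[InteractionNetwork, pd.Series]:
    """Planted-partition interaction network.

    Risk genes (positives and candidates) are spread round-robin over the
    first ``n_positive_communities`` communities; the remaining genes are
    assigned uniformly over all communities.  Edge confidences are uniform on
    [conf_low, conf_high], so a tunable fraction falls below the 0.4 filter.
    Returns the network and the per-gene community assignment.
    """
    config.validate()
    rng = _rng(config, 2)
    genes = np.array(gene_ids(config))
    n = len(genes)
    comm = np.empty(n, dtype=int)
    risk = (labels["is_positive"] | labels["is_candidate"]).to_numpy()
    risk_idx = np.flatnonzero(risk)
    comm[risk_idx] = np.arange(len(risk_idx)) % config.n_positive_communities
    rest = np.flatnonzero(~risk)
    comm[rest] = rng.integers(0, config.n_communities, size=len(rest))

    same = comm[:, None] == comm[None, :]
    prob = np.where(same, config.p_within, config.p_between)
    iu, ju = np.triu_indices(n, k=1)
    draw = rng.random(size=len(iu))
    keep = draw < prob[iu, ju]
    ia, ib = iu[keep], ju[keep]
    scores = rng.uniform(config.conf_low, config.conf_high, size=len(ia))
    net = InteractionNetwork.from_arrays(genes[ia], genes[ib], scores, nodes=genes)
    communities = pd.Series(comm, index=pd.Index(genes, name="gene"), name="community")
    return net, communities


# ---------------------------------------------------------------------------
# Evaluation panel
# ---------------------------------------------------------------------------


@dataclass
class EvalData:
    priors: pd.DataFrame
    dnm: pd.DataFrame
    eqtl: pd.DataFrame
    pli: pd.Series


def simulate_evaluation_data(
    config: SimulationConfig,
    labels: pd.DataFrame,
    scores: pd.Series | None = None,
    communities: pd.Series | None = None,
) -> EvalData:
    """Generate the prior panel, DNM table, eQTL/GWAS table and pLI values.

    ``scores`` drives the eQTL hit probabilities (top ``eqtl_top_fraction``
    of genes get ``eqtl_hit_high``); when omitted, a noisy label proxy is
    used.  ``communities`` (from :func:`simulate_network`) elevates pLI in
    the risk communities; when omitted, pLI is elevated in positives.
    """
    config.validate()
    rng = _rng(config, 3)
    genes = labels.index
    n = len(genes)
    signal = np.where(
        labels["is_positive"], 1.0, np.where(labels["is_candidate"], config.candidate_effect, 0.0)
    )

    # -- priors ------------------------------------------------------------
    from scipy.stats import norm

    priors = pd.DataFrame(index=genes)
    for col in ("DAWN", "Krishnan", "DAMAGES", "TADA_BF"):
        priors[col] = config.prior_effect * signal + rng.normal(0.0, 1.0, size=n)
    for col in PRIOR_COLUMNS:
        if col.startswith("tadaFdr"):
            z = config.prior_effect * signal + rng.normal(0.0, 1.0, size=n)
            priors[col] = norm.sf(z)  # FDR-like: uniform under null, small for signal
    priors = priors[list(PRIOR_COLUMNS)]
    for col in PRIOR_COLUMNS:
        rate = config.prior_missingness.get(col, 0.0)
        if rate > 0:
            mask = rng.random(size=n) < rate
            priors.loc[mask, col] = np.nan

    # -- DNM table ---------------------------------------------------------
    length = rng.lognormal(mean=0.0, sigma=config.length_sd, size=n)
    length = length / length.mean()  # relative mutational target size
    lam_syn = config.syn_rate * length
    lof_mult = np.where(labels["is_positive"], config.lof_enrichment, 1.0)
    mis_mult = np.where(labels["is_positive"], config.missense_enrichment, 1.0)
    lam_lof = config.lof_rate * length * lof_mult
    lam_mis = config.missense_rate * length * mis_mult

    cohorts = np.array(["MSSNG", "SPARK", "ASC"])
    records = []
    for consequence, lam in (
        ("synonymous", lam_syn),
        ("LOF", lam_lof),
        ("missense", lam_mis),
    ):
        counts = rng.poisson(lam)
        hit_genes = np.repeat(np.arange(n), counts)
        probands = rng.integers(0, config.n_probands, size=len(hit_genes))
        cohort = cohorts[rng.integers(0, 3, size=len(hit_genes))]
        for g, p, c in zip(hit_genes, probands, cohort):
            records.append((genes[g], f"P{p:05d}", c, consequence))
    dnm = pd.DataFrame(records, columns=["gene", "individual", "cohort", "consequence"])
    dnm = fio.validate_dnm_table(dnm)

    # -- eQTL / GWAS -------------------------------------------------------
    if scores is None:
        scores = pd.Series(signal + rng.normal(0.0, 0.1, size=n), index=genes)
    order = scores.reindex(genes).to_numpy(float)
    n_top = max(1, int(round(config.eqtl_top_fraction * n)))
    top_cut = np.sort(order)[::-1][n_top - 1]
    hit_prob = np.where(order >= top_cut, config.eqtl_hit_high, config.eqtl_hit_low)
    n_records = rng.poisson(config.eqtl_per_gene, size=n)
    gene_of_record = np.repeat(np.arange(n), n_records)
    hits = rng.random(size=len(gene_of_record)) < hit_prob[gene_of_record]
    gwas_p = np.where(
        hits,
        rng.uniform(0.0, config.gwas_cut, size=len(gene_of_record)),
        rng.uniform(config.gwas_cut, 1.0, size=len(gene_of_record)),
    )
    gwas_p = np.clip(gwas_p, 1e-300, 1.0)
    eqtl = pd.DataFrame(
        {
            "snp": [f"rs{i + 1:06d}" for i in range(len(gene_of_record))],
            "gene": genes.to_numpy()[gene_of_record],
            "gwas_p": gwas_p,
        }
    )

    # -- pLI ---------------------------------------------------------------
    if communities is not None:
        in_risk_comm = communities.reindex(genes).to_numpy() < config.n_positive_communities
    else:
        in_risk_comm = labels["is_positive"].to_numpy()
    a_hi, b_hi = config.pli_high
    a_lo, b_lo = config.pli_low
    pli_vals = np.where(
        in_risk_comm,
        rng.beta(a_hi, b_hi, size=n),
        rng.beta(a_lo, b_lo, size=n),
    )
    pli = pd.Series(pli_vals, index=genes, name="pLI")

    return EvalData(priors=priors, dnm=dnm, eqtl=eqtl, pli=pli)


# ---------------------------------------------------------------------------
# Whole-study convenience + on-disk dialect
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    bundle: ExpressionBundle
    labels: pd.DataFrame
    network: InteractionNetwork
    communities: pd.Series
    eval_data: EvalData

    @property
    def positives(self) -> set[str]:
        return set(self.labels.index[self.labels["is_positive"]])

    @property
    def candidates(self) -> set[str]:
        return set(self.labels.index[self.labels["is_candidate"]])

    @property
    def exclusion(self) -> set[str]:
        """Genes barred from the negative pool (database-listed analogue)."""
        return self.positives | self.candidates


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate every input for one end-to-end run."""
    bundle, labels = simulate_expression(config)
    network, communities = simulate_network(config, labels)
    eval_data = simulate_evaluation_data(config, labels, communities=communities)
    return SimulatedStudy(
        config=config,
        bundle=bundle,
        labels=labels,
        network=network,
        communities=communities,
        eval_data=eval_data,
    )


def write_study(study: SimulatedStudy, out_dir) -> dict:
    """Write a complete input directory in the dialects the readers consume,
    plus a manifest JSON with the resolved config.  Returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fio.write_expression_bundle(
        study.bundle,
        out / "expression_matrix.csv",
        out / "rows_metadata.csv",
        out / "columns_metadata.csv",
    )
    fio.write_edge_list(study.network, out / "edges.tsv")
    fio.write_gene_table(study.eval_data.priors, out / "priors.tsv")
    fio.write_gene_table(study.eval_data.pli.to_frame(), out / "pli.tsv")
    fio.write_dnm_table(study.eval_data.dnm, out / "dnm.tsv")
    fio.write_eqtl_table(study.eval_data.eqtl, out / "eqtl.tsv")
    lab = study.labels.copy()
    lab["community"] = study.communities
    fio.write_gene_table(lab, out / "labels.tsv")
    (out / "positives.txt").write_text("\n".join(sorted(study.positives)) + "\n")
    (out / "exclusion.txt").write_text("\n".join(sorted(study.exclusion)) + "\n")
    manifest = {
        "config": dataclasses.asdict(study.config),
        "files": {
            "expression_matrix": "expression_matrix.csv",
            "rows_metadata": "rows_metadata.csv",
            "columns_metadata": "columns_metadata.csv",
            "edges": "edges.tsv",
            "priors": "priors.tsv",
            "pli": "pli.tsv",
            "dnm": "dnm.tsv",
            "eqtl": "eqtl.tsv",
            "labels": "labels.tsv",
            "positives": "positives.txt",
            "exclusion": "exclusion.txt",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
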