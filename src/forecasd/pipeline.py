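"""Two-level stacked ensemble orchestration.

Level 1 trains two balanced random forests — one on developmental expression
trajectory features, one on interaction-network shortest-path features —
using established risk genes as positives and randomly sampled non-listed
genes as negatives.  Their genome-wide scores (out-of-bag for training
genes, so the stack never sees a self-prediction) join a panel of prior
gene-level scores as the ten meta-features of the level-2 forest, whose
positive-vote fraction is the final per-gene score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MissingColumnError, ValidationError
from .expression import build_trajectory_features, filter_regions
from .forest import (
    EliminationResult,
    ForestModel,
    ForestParams,
    backward_eliminate,
    score_genes,
    train_balanced_forest,
)
from .io import ExpressionBundle, InteractionNetwork
from .network import filter_edges, shortest_path_matrix

logger = logging.getLogger(__name__)

#: fixed meta-feature column order of the level-2 model
META_COLUMNS = [
    "BrainSpan_score",
    "STRING_score",
    "DAWN",
    "Krishnan",
    "DAMAGES",
    "TADA_BF",
    "tadaFdrAscSscExomeSscAgpSmallDel",
    "tadaFdrAscSscExome",
    "tadaFdrAscExome",
    "tadaFdrSscExome",
]

#: output score-table column order
SCORE_COLUMNS = ["BrainSpan_score", "STRING_score", "forecASD", "is_training", "oob"]

_STAGE_IDS = {"labels": 0, "brainspan": 1, "string": 2, "meta": 3}


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) fanned out from one top-level
    seed, so stages can be rerun independently yet reproducibly."""
    ss = np.random.SeedSequence((int(base_seed), _STAGE_IDS[stage]))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelSet:
    """Training labels: positive gene set and sampled negative set."""

    positives: tuple[str, ...]
    negatives: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValidationError("positives and negatives overlap")

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.positives) | set(self.negatives))

    def y(self, index: pd.Index) -> pd.Series:
        pos = set(self.positives)
        return pd.Series([1 if g in pos else 0 for g in index], index=index, name="y")


def make_training_labels(
    positives, exclusion, universe, n_negative: int = 1000, seed: int = 0
) -> LabelSet:
    """Sample the negative class uniformly without replacement from the
    universe minus positives minus the exclusion list."""
    positives = set(positives)
    exclusion = set(exclusion)
    universe = set(universe)
    if not positives <= universe:
        raise ValidationError("positives must be a subset of the universe")
    candidates = sorted(universe - positives - exclusion)
    if len(candidates) < n_negative:
        raise ValidationError(
            f"only {len(candidates)} candidate negatives available, need {n_negative}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    negatives = rng.choice(np.array(candidates, dtype=object), size=n_negative, replace=False)
    return LabelSet(
        positives=tuple(sorted(positives)),
        negatives=tuple(sorted(negatives)),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Meta features
# ---------------------------------------------------------------------------


@dataclass
class MetaFeatureTable:
    """Level-2 feature table: ten named columns in fixed order, fully
    imputed, plus per-cell imputation flags."""

    values: pd.DataFrame
    imputed: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != META_COLUMNS:
            raise ValidationError("meta-feature columns out of order")
        if self.values.isna().any().any():
            raise ValidationError("meta-feature table contains missing values")
        for col in ("BrainSpan_score", "STRING_score"):
            v = self.values[col].to_numpy(float)
            if not np.all((v >= 0) & (v <= 1)):
                raise ValidationError(f"{col} outside [0, 1]")


def assemble_meta_features(
    base_scores: pd.DataFrame, priors: pd.DataFrame, labels: LabelSet
) -> MetaFeatureTable:
    """Join level-1 scores with the prior panel over the scored-gene universe
    (genes with at least one base score); impute each missing value with the
    training-set median of its column and flag it."""
    for col in ("BrainSpan_score", "STRING_score"):
        if col not in base_scores.columns:
            raise MissingColumnError(f"base scores lack column {col!r}")
    universe = base_scores.index[base_scores[["BrainSpan_score", "STRING_score"]].notna().any(axis=1)]
    if len(universe) == 0:
        raise DegenerateInputError("no gene has a level-1 score")
    missing_priors = [c for c in META_COLUMNS[2:] if c not in priors.columns]
    if missing_priors:
        raise MissingColumnError(f"prior table lacks column {missing_priors[0]!r}")

    table = pd.concat(
        [
            base_scores.loc[universe, ["BrainSpan_score", "STRING_score"]],
            priors.reindex(universe)[META_COLUMNS[2:]],
        ],
        axis=1,
    )[META_COLUMNS]
    flags = table.isna()
    train_genes = [g for g in labels.genes if g in table.index]
    medians = table.loc[train_genes].median()
    fallback = table.median()
    for col in META_COLUMNS:
        fill = medians[col]
        if pd.isna(fill):
            fill = fallback[col]
        if pd.isna(fill):
            raise DegenerateInputError(f"column {col!r} has no observed value to impute from")
        table[col] = table[col].fillna(fill)
    return MetaFeatureTable(values=table, imputed=flags)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Tunables of one end-to-end run; the single ``seed`` fans out to the
    label-sampling and the three forest stages."""

    seed: int = 0
    n_negative: int = 1000
    n_trees: int = 1000
    per_class: int = 70
    min_region_samples: int = 20
    grid_size: int = 50
    min_edge_score: float = 0.4
    scale_orientation: str = "gene"


@dataclass
class PipelineResult:
    scores: pd.DataFrame  # SCORE_COLUMNS, indexed by gene
    importances: pd.Series  # level-2 feature importances, sums to 1
    labels: LabelSet
    meta: MetaFeatureTable
    base_scores: pd.DataFrame
    elimination: EliminationResult
    models: dict[str, ForestModel]


def run_pipeline(
    bundle: ExpressionBundle,
    network: InteractionNetwork,
    priors: pd.DataFrame,
    positives,
    exclusion,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full two-level ensemble and emit the gene score table.

    Stages: region filter -> trajectory features -> expression forest;
    confidence filter -> shortest-path matrix -> backward elimination ->
    network forest; OOB-aware scoring of both; meta-feature assembly;
    level-2 forest; final genome-wide scores.  Fully deterministic given the
    config seed.
    """
    config = config or PipelineConfig()
    positives = set(positives)
    exclusion = set(exclusion)

    # --- level 1: expression ------------------------------------------------
    traj = build_trajectory_features(
        filter_regions(bundle, config.min_region_samples),
        grid_size=config.grid_size,
        scale=config.scale_orientation,
    )

    # --- level 1: network ---------------------------------------------------
    spm = shortest_path_matrix(filter_edges(network, config.min_edge_score))
    string_feats = spm.feature_frame()

    # --- labels -------------------------------------------------------------
    expr_genes = set(traj.index)
    net_genes = set(string_feats.index)
    both = expr_genes & net_genes
    positives_used = sorted(positives & both)
    if not positives_used:
        raise DegenerateInputError(
            "no positive gene is present in both the expression and network data"
        )
    if len(positives_used) < len(positives):
        logger.info(
            "%d/%d positives present in both data sources",
            len(positives_used),
            len(positives),
        )
    labels = make_training_labels(
        positives_used,
        exclusion | positives,
        universe=both,
        n_negative=config.n_negative,
        seed=stage_seed(config.seed, "labels"),
    )
    train_genes = labels.genes
    y = labels.y(pd.Index(train_genes))

    # --- fit + score level-1 models ------------------------------------------
    bs_params = ForestParams(
        n_trees=config.n_trees, per_class=config.per_class, seed=stage_seed(config.seed, "brainspan")
    )
    bs_model = train_balanced_forest(traj.loc[train_genes], y, bs_params)
    bs_scores, bs_oob = score_genes(bs_model, traj)

    st_params = ForestParams(
        n_trees=config.n_trees, per_class=config.per_class, seed=stage_seed(config.seed, "string")
    )
    elimination = backward_eliminate(string_feats.loc[train_genes], y, st_params)
    st_scores, st_oob = score_genes(elimination.model, string_feats[elimination.selected])

    universe = sorted(expr_genes | net_genes)
    base_scores = pd.DataFrame(
        {
            "BrainSpan_score": bs_scores.reindex(universe),
            "STRING_score": st_scores.reindex(universe),
        },
        index=pd.Index(universe, name="gene"),
    )

    # --- level 2 --------------------------------------------------------------
    meta = assemble_meta_features(base_scores, priors, labels)
    meta_params = ForestParams(
        n_trees=config.n_trees, per_class=config.per_class, seed=stage_seed(config.seed, "meta")
    )
    meta_model = train_balanced_forest(meta.values.loc[train_genes], y, meta_params)
    final_scores, final_oob = score_genes(meta_model, meta.values)

    is_training = meta.values.index.isin(train_genes)
    scores = pd.DataFrame(
        {
            "BrainSpan_score": base_scores["BrainSpan_score"].reindex(meta.values.index),
            "STRING_score": base_scores["STRING_score"].reindex(meta.values.index),
            "forecASD": final_scores,
            "is_training": is_training,
            "oob": final_oob.to_numpy(),
        },
        index=meta.values.index,
    )[SCORE_COLUMNS]

    return PipelineResult(
        scores=scores,
        importances=meta_model.feature_importances(),
        labels=labels,
        meta=meta,
        base_scores=base_scores,
        elimination=elimination,
        models={"brainspan": bs_model, "string": elimination.model, "meta": meta_model},
    )
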