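"""Balanced random forest with exact per-tree class sampling and OOB scoring.

Each tree is grown on an in-bag of exactly ``per_class`` draws from the
positive class and ``per_class`` draws from the negative class (with
replacement within class, the stratified-bootstrap convention).  The in-bag
multiset of every tree is recorded, which makes three things possible and
exactly reproducible:

* out-of-bag (OOB) scores for training rows — the positive-vote fraction over
  only those trees whose in-bag excluded the row;
* per-feature split-usage counts across the whole forest;
* the backward-elimination loop that repeatedly drops features never used in
  any tree until every retained feature is used at least once.

The individual trees are scikit-learn decision trees (Gini impurity,
``mtry = floor(sqrt(p))`` candidate features per split, nodes grown to
purity); the balanced bagging, bookkeeping, scoring and elimination logic
live here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import ValidationError

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class ForestParams:
    """Training parameters for one balanced forest.

    ``mtry=None`` resolves to ``floor(sqrt(n_features))`` at fit time.
    ``replace=False`` switches to within-class sampling without replacement
    (then ``per_class`` must not exceed either class size).
    """

    n_trees: int = 1000
    per_class: int = 70
    mtry: int | None = None
    replace: bool = True
    min_samples_leaf: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.per_class < 1:
            raise ValidationError("per_class must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValidationError("mtry must be >= 1 when given")


@dataclass
class ForestModel:
    """A fitted balanced forest plus the bookkeeping needed for OOB scoring.

    ``in_bag[t, i]`` counts how often training row ``i`` was drawn into the
    in-bag of tree ``t`` (rows are identified by ``training_ids``).
    """

    trees: list = field(repr=False)
    in_bag: np.ndarray = field(repr=False)
    feature_names: list[str] = field(default_factory=list)
    training_ids: pd.Index = field(default_factory=pd.Index)
    y_train: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    params: ForestParams = field(default_factory=ForestParams)
    mtry_resolved: int = 1

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def feature_usage(self) -> pd.Series:
        """Number of internal split nodes using each feature, summed over
        all trees."""
        counts = np.zeros(len(self.feature_names), dtype=np.int64)
        for tree in self.trees:
            feats = tree.tree_.feature
            used = feats[feats >= 0]
            np.add.at(counts, used, 1)
        return pd.Series(counts, index=self.feature_names, name="usage")

    def feature_importances(self) -> pd.Series:
        """Mean impurity-decrease importances, normalized to sum to 1."""
        imp = np.zeros(len(self.feature_names), dtype=float)
        for tree in self.trees:
            imp += tree.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        return pd.Series(imp, index=self.feature_names, name="importance")


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, np.array([0, 1])):
        raise ValidationError(
            f"labels must contain both classes 0 and 1, got classes {classes.tolist()}"
        )
    return y


def train_balanced_forest(X: pd.DataFrame, y, params: ForestParams | None = None) -> ForestModel:
    """Fit a balanced forest on feature matrix ``X`` (rows indexed by gene)
    and binary labels ``y`` aligned with ``X``'s rows.

    Each tree's in-bag holds exactly ``per_class`` positive and ``per_class``
    negative draws.  Identical (X, y, params) give identical forests.
    """
    params = params or ForestParams()
    params.validate()
    if isinstance(y, pd.Series):
        y = y.reindex(X.index).to_numpy()
    y = _check_labels(np.asarray(y))
    if len(y) != len(X):
        raise ValidationError("y length does not match X rows")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if not params.replace and params.per_class > min(len(pos), len(neg)):
        raise ValidationError(
            "per_class exceeds a class size and sampling is without replacement"
        )
    p = X.shape[1]
    if p == 0:
        raise ValidationError("feature matrix has no columns")
    mtry = params.mtry if params.mtry is not None else max(1, int(math.isqrt(p)))
    mtry = min(mtry, p)

    Xv = np.ascontiguousarray(X.to_numpy(dtype=np.float32))
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    tree_states = rng.integers(0, 2**31 - 1, size=params.n_trees)

    trees: list[DecisionTreeClassifier] = []
    in_bag = np.zeros((params.n_trees, len(y)), dtype=np.uint16)
    for t in range(params.n_trees):
        ip = rng.choice(pos, size=params.per_class, replace=params.replace)
        ineg = rng.choice(neg, size=params.per_class, replace=params.replace)
        rows = np.concatenate([ip, ineg])
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            min_samples_leaf=params.min_samples_leaf,
            random_state=int(tree_states[t]),
        )
        tree.fit(Xv[rows], y[rows])
        trees.append(tree)
        np.add.at(in_bag[t], rows, 1)

    return ForestModel(
        trees=trees,
        in_bag=in_bag,
        feature_names=list(X.columns),
        training_ids=X.index.copy(),
        y_train=y.astype(np.int8),
        params=params,
        mtry_resolved=mtry,
    )


def _tree_votes(model: ForestModel, Xv: np.ndarray) -> np.ndarray:
    """Boolean (n_trees, n_rows) matrix of positive votes."""
    votes = np.empty((model.n_trees, Xv.shape[0]), dtype=bool)
    for t, tree in enumerate(model.trees):
        votes[t] = tree.predict(Xv) == 1
    return votes


def score_genes(model: ForestModel, X: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Score every row of ``X`` as a positive-vote fraction in [0, 1].

    Rows whose identifier matches a training row are scored out-of-bag: only
    trees whose in-bag excluded that row vote.  A training row that happens
    to be in-bag in every tree falls back to the all-trees score with a
    logged warning.  Returns ``(scores, oob_flag)`` aligned with ``X``.
    """
    if list(X.columns) != model.feature_names:
        raise ValidationError("feature columns do not match the fitted model")
    Xv = np.ascontiguousarray(X.to_numpy(dtype=np.float32))
    votes = _tree_votes(model, Xv)
    scores = votes.mean(axis=0)
    oob = np.zeros(len(X), dtype=bool)

    train_pos = model.training_ids.get_indexer(X.index)  # -1 where not training
    rows_in_x = np.flatnonzero(train_pos >= 0)
    if len(rows_in_x):
        bag = model.in_bag[:, train_pos[rows_in_x]]  # (n_trees, n_train_rows)
        out_mask = bag == 0
        denom = out_mask.sum(axis=0)
        numer = (votes[:, rows_in_x] & out_mask).sum(axis=0)
        ok = denom > 0
        scores[rows_in_x[ok]] = numer[ok] / denom[ok]
        oob[rows_in_x[ok]] = True
        if np.any(~ok):
            n_bad = int((~ok).sum())
            logger.warning(
                "%d training row(s) were in-bag in every tree; falling back to "
                "the all-trees score for them",
                n_bad,
            )
    return (
        pd.Series(scores, index=X.index, name="score"),
        pd.Series(oob, index=X.index, name="oob"),
    )


def _round_seed(base_seed: int, round_index: int) -> int:
    """Deterministic per-round seed for the elimination loop (< 2**31)."""
    ss = np.random.SeedSequence((int(base_seed), int(round_index)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class EliminationResult:
    selected: list[str]
    model: ForestModel
    history: pd.DataFrame  # columns: round, n_features, n_used, seed


def backward_eliminate(X: pd.DataFrame, y, params: ForestParams | None = None) -> EliminationResult:
    """Iterated fit-and-drop feature selection.

    Each round fits a balanced forest, counts per-feature split usage across
    all trees, and drops every feature with zero usage; the loop stops when
    every retained feature is used at least once.  Rounds use fresh seeds
    derived deterministically from (base seed, round index).
    """
    params = params or ForestParams()
    params.validate()
    cols = list(X.columns)
    rows = []
    model: ForestModel | None = None
    r = 0
    while True:
        round_params = replace(params, seed=_round_seed(params.seed, r))
        model = train_balanced_forest(X[cols], y, round_params)
        usage = model.feature_usage()
        used = usage.index[usage > 0].tolist()
        rows.append(
            {"round": r, "n_features": len(cols), "n_used": len(used), "seed": round_params.seed}
        )
        if len(used) == 0:
            raise ValidationError("backward elimination removed every feature")
        if len(used) == len(cols):
            break
        cols = used
        r += 1
    history = pd.DataFrame(rows)
    return EliminationResult(selected=cols, model=model, history=history)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: ForestModel, path) -> None:
    """Persist a fitted forest (params, trees, in-bag masks) as a versioned
    joblib archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": model.params,
        "trees": model.trees,
        "in_bag": model.in_bag,
        "feature_names": model.feature_names,
        "training_ids": list(model.training_ids),
        "y_train": model.y_train,
        "mtry_resolved": model.mtry_resolved,
    }
    joblib.dump(payload, path)


def load_model(path) -> ForestModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(f"unsupported model archive version: {version!r}")
    return ForestModel(
        trees=payload["trees"],
        in_bag=payload["in_bag"],
        feature_names=payload["feature_names"],
        training_ids=pd.Index(payload["training_ids"]),
        y_train=payload["y_train"],
        params=payload["params"],
        mtry_resolved=payload["mtry_resolved"],
    )
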