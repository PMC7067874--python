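"""Developmental expression trajectory features.

Turns an irregular, redundant gene x sample expression matrix into a fixed
gene x (region x timepoint) feature matrix: per gene and region, replicate
ages are averaged, the trajectory is LOWESS-smoothed, linearly interpolated
onto a shared grid of post-conception-week timepoints, and the concatenated
per-gene vector is z-scaled.  With the reference atlas (16 retained regions,
50 grid points) this yields 800 features per gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import DegenerateInputError, ValidationError
from .io import ExpressionBundle

#: classical LOWESS defaults of the smoother the trajectories are fit with
LOWESS_FRAC = 2.0 / 3.0
LOWESS_ITERATIONS = 3

DEFAULT_GRID_SIZE = 50
DEFAULT_MIN_REGION_SAMPLES = 20


def filter_regions(bundle: ExpressionBundle, min_samples: int = DEFAULT_MIN_REGION_SAMPLES) -> ExpressionBundle:
    """Drop every sample whose brain region has fewer than ``min_samples``
    samples (a region with exactly ``min_samples`` is retained)."""
    if min_samples < 1:
        raise ValidationError("min_samples must be >= 1")
    counts = bundle.sample_meta["region"].value_counts()
    keep_regions = set(counts.index[counts >= min_samples])
    if not keep_regions:
        raise ValidationError(
            f"no region has >= {min_samples} samples (max observed: {int(counts.max())})"
        )
    keep = bundle.sample_meta.index[bundle.sample_meta["region"].isin(keep_regions)]
    return bundle.subset_samples(keep)


def smooth_interpolate_trajectory(
    ages,
    values,
    grid,
    frac: float = LOWESS_FRAC,
    robustness_iters: int = LOWESS_ITERATIONS,
) -> np.ndarray:
    """Smooth one (age, expression) trajectory and resample it onto ``grid``.

    Replicate measurements at an identical age are mean-averaged first, the
    averaged points are LOWESS-smoothed (span ``frac``, ``robustness_iters``
    robustness iterations), and the smoothed curve is linearly interpolated
    onto the grid.  Grid points outside the observed age range take the
    nearest smoothed endpoint value (constant extension).

    Numerical notes: a constant trajectory is returned as-is; with fewer than
    four distinct ages the averaged points are interpolated directly (a local
    regression with the full span is the straight line through them anyway);
    robustness iterations are skipped when the initial fit already
    interpolates the data exactly, which avoids 0/0 robustness weights on
    exactly collinear input.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if ages.shape != values.shape:
        raise ValidationError("ages and values must have the same length")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be strictly ascending")
    ok = np.isfinite(values)
    ages, values = ages[ok], values[ok]

    # average replicates at identical ages
    order = np.argsort(ages, kind="stable")
    ages, values = ages[order], values[order]
    uniq, inverse = np.unique(ages, return_inverse=True)
    if len(uniq) < 2:
        raise DegenerateInputError(
            f"need >= 2 distinct ages after replicate averaging, got {len(uniq)}"
        )
    sums = np.bincount(inverse, weights=values, minlength=len(uniq))
    cnts = np.bincount(inverse, minlength=len(uniq))
    means = sums / cnts

    if np.allclose(means, means[0], rtol=0.0, atol=1e-12 * max(1.0, abs(means[0]))):
        return np.full(grid.shape, means[0], dtype=float)

    if len(uniq) < 4:
        smoothed_x, smoothed_y = uniq, means
    else:
        fit0 = _sm_lowess(means, uniq, frac=frac, it=0, return_sorted=True)
        resid = means - fit0[:, 1]
        scale = np.max(np.abs(means)) or 1.0
        if np.max(np.abs(resid)) <= 1e-10 * scale or robustness_iters == 0:
            smoothed_x, smoothed_y = fit0[:, 0], fit0[:, 1]
        else:
            fit = _sm_lowess(means, uniq, frac=frac, it=robustness_iters, return_sorted=True)
            smoothed_x, smoothed_y = fit[:, 0], fit[:, 1]

    out = np.interp(grid, smoothed_x, smoothed_y)  # constant extension at ends
    if not np.all(np.isfinite(out)):
        raise ValidationError("smoothed trajectory contains non-finite values")
    return out


def feature_names(regions, grid_size: int) -> list[str]:
    """Column names ``<region>@t<01..grid_size>``, regions lexicographic."""
    return [f"{r}@t{i:02d}" for r in sorted(regions) for i in range(1, grid_size + 1)]


def build_trajectory_features(
    bundle: ExpressionBundle,
    grid_size: int = DEFAULT_GRID_SIZE,
    scale: str = "gene",
) -> pd.DataFrame:
    """Build the gene x (region x timepoint) trajectory feature matrix.

    One shared grid of ``grid_size`` equally spaced pcw values spans the
    global min..max age over all samples in the (already region-filtered)
    bundle.  Per gene and region the trajectory is smoothed and resampled via
    :func:`smooth_interpolate_trajectory`; the concatenated per-gene vector is
    then z-scaled (``scale="gene"``, the default: each non-constant gene row
    ends with mean 0, sd 1; constant rows map to all zeros).
    ``scale="timepoint"`` z-scales each feature column instead — the
    alternative reading of the scaling step, kept as a switch.

    Column order is regions sorted lexicographically, grid index ascending
    within region, so the output is reproducible byte-for-byte.
    """
    if grid_size < 2:
        raise ValidationError("grid_size must be >= 2")
    if scale not in ("gene", "timepoint"):
        raise ValidationError(f"scale must be 'gene' or 'timepoint', got {scale!r}")
    meta = bundle.sample_meta
    ages_all = meta["age_pcw"].to_numpy(float)
    grid = np.linspace(ages_all.min(), ages_all.max(), grid_size)
    regions = sorted(meta["region"].unique())
    genes = bundle.genes
    blocks: list[np.ndarray] = []
    for region in regions:
        samples = meta.index[meta["region"] == region]
        ages = meta.loc[samples, "age_pcw"].to_numpy(float)
        mat = bundle.values.loc[:, samples].to_numpy(float)
        block = np.empty((len(genes), grid_size), dtype=float)
        for i in range(len(genes)):
            row = mat[i]
            if not np.any(np.isfinite(row)):
                raise ValidationError(
                    f"gene {genes[i]!r} has no values in region {region!r}"
                )
            block[i] = smooth_interpolate_trajectory(ages, row, grid)
        blocks.append(block)
    features = np.hstack(blocks)

    if scale == "gene":
        mean = features.mean(axis=1, keepdims=True)
        sd = features.std(axis=1, ddof=1, keepdims=True)
        const = sd[:, 0] <= 1e-15 * np.maximum(1.0, np.abs(mean[:, 0]))
        sd[const, 0] = 1.0
        features = (features - mean) / sd
        features[const, :] = 0.0
    else:
        mean = features.mean(axis=0, keepdims=True)
        sd = features.std(axis=0, ddof=1, keepdims=True)
        const = sd[0] <= 1e-15 * np.maximum(1.0, np.abs(mean[0]))
        sd[0, const] = 1.0
        features = (features - mean) / sd
        features[:, const] = 0.0

    return pd.DataFrame(
        features, index=genes.copy(), columns=feature_names(regions, grid_size)
    )
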