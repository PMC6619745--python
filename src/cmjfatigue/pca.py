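"""Stratified PCA of CMJ features.

The four concentric features are stratified by the eight measurement time
points, giving 32 variables per sample; each sample is one jump repetition
of one athlete under one workload (jump k before training is paired with
jump k at every later time point), so the default study design yields
150 samples.  Each column is centred and scaled before the decomposition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA
from sklearn.metrics import silhouette_score

from .processing import FEATURE_COLUMNS
from .synthetic import TIME_LABELS

logger = logging.getLogger(__name__)


@dataclass
class StratifiedMatrix:
    """Samples x (feature x time-point) matrix, column-standardised.

    ``values`` holds the centred/scaled data; the raw column means and
    scales are retained so new data can be projected consistently.
    """

    values: np.ndarray            # (n_samples, n_features*n_times), standardised
    columns: list[str]            # "<feature>@<time label>", feature-major
    index: pd.DataFrame           # athlete_id, workload[, jump] per row
    means: np.ndarray
    scales: np.ndarray
    n_dropped: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PCAResult:
    loadings: np.ndarray      # (p, k), orthonormal columns
    scores: np.ndarray        # (n, k) = standardised data @ loadings
    proportions: np.ndarray   # explained-variance proportion per PC
    columns: list[str]
    index: pd.DataFrame

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def build_matrix(
    features: pd.DataFrame,
    time_labels: tuple[str, ...] = TIME_LABELS,
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
    pairing: str = "repetition",
) -> StratifiedMatrix:
    """Pivot a long feature table into the stratified wide matrix.

    ``pairing='repetition'`` keys samples on (athlete, workload, jump);
    ``'session_mean'`` averages the jumps first, keying on (athlete,
    workload).  Rows missing any feature x time cell are dropped (logged).
    Standardisation uses ddof=1, matching the usual correlation-PCA
    convention; a constant column is an error.
    """
    if pairing not in ("repetition", "session_mean"):
        raise ValueError(f"unknown pairing {pairing!r}")
    df = features.copy()
    if pairing == "session_mean":
        df = (
            df.groupby(["athlete_id", "workload", "time_point"], as_index=False)[
                list(feature_columns)
            ].mean()
        )
        keys = ["athlete_id", "workload"]
    else:
        keys = ["athlete_id", "workload", "jump"]

    wide = df.pivot_table(
        index=keys, columns="time_point", values=list(feature_columns), sort=False
    )
    # deterministic feature-major column order, time within feature
    cols = [(f, t) for f in feature_columns for t in time_labels]
    missing = [c for c in cols if c not in wide.columns]
    if missing:
        raise ValueError(f"feature table lacks cells for {missing[:4]}...")
    wide = wide[cols]
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.info("build_matrix dropped %d incomplete sample rows", n_dropped)
    if complete.empty:
        raise ValueError("no complete samples after dropping rows with missing cells")

    values = complete.to_numpy(dtype=float)
    means = values.mean(axis=0)
    scales = values.std(axis=0, ddof=1)
    names = [f"{f}@{t}" for f, t in cols]
    constant = np.nonzero(scales <= 1e-12 * np.maximum(np.abs(means), 1.0))[0]
    if constant.size:
        raise ValueError(f"constant column(s): {[names[i] for i in constant]}")
    return StratifiedMatrix(
        values=(values - means) / scales,
        columns=names,
        index=complete.index.to_frame(index=False),
        means=means,
        scales=scales,
        n_dropped=n_dropped,
    )


def run_pca(matrix: StratifiedMatrix) -> PCAResult:
    """Centred+scaled PCA (correlation structure); PCs ordered by decreasing
    variance; each loading vector is flipped so its largest-magnitude element
    is positive (eigenvector signs are otherwise arbitrary)."""
    n, p = matrix.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 sample rows")
    pca = _SKPCA(n_components=min(n, p), svd_solver="full")
    pca.fit(matrix.values)
    loadings = pca.components_.T.copy()
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip
    scores = matrix.values @ loadings
    return PCAResult(
        loadings=loadings,
        scores=scores,
        proportions=pca.explained_variance_ratio_.copy(),
        columns=list(matrix.columns),
        index=matrix.index.copy(),
    )


def cumulative_variance(result: PCAResult, k: int) -> float:
    """Proportion of variance explained by the first k PCs."""
    if not 1 <= k <= result.n_components:
        raise ValueError(f"k={k} outside [1, {result.n_components}]")
    return float(result.proportions[:k].sum())


@dataclass
class CapabilityMap:
    """Scores on a PC pair with group labels — the athlete 'capability map'."""

    scores: pd.DataFrame       # group label + the two PC columns per sample
    centroids: pd.DataFrame    # per-group centroid on the PC pair
    dispersions: pd.Series     # per-group mean squared distance to centroid


def capability_map(
    result: PCAResult, pcs: tuple[int, int] = (1, 2), group_by: str = "athlete_id"
) -> CapabilityMap:
    """Group the scores on a pair of PCs (1-based indices) by athlete or
    workload, with per-group centroids and dispersions, ready for plotting."""
    for pc in pcs:
        if not 1 <= pc <= result.n_components:
            raise ValueError(f"PC index {pc} out of range")
    if group_by not in result.index.columns:
        raise ValueError(f"unknown grouping column {group_by!r}")
    cols = [f"PC{p}" for p in pcs]
    df = result.index[[group_by]].copy()
    for name, pc in zip(cols, pcs):
        df[name] = result.scores[:, pc - 1]
    centroids = df.groupby(group_by)[cols].mean()
    sq = ((df[cols] - centroids.loc[df[group_by]].to_numpy()) ** 2).sum(axis=1)
    dispersions = sq.groupby(df[group_by]).mean()
    return CapabilityMap(df, centroids, dispersions)


def score_silhouette(result: PCAResult, pcs: tuple[int, int], labels: np.ndarray) -> float:
    """Mean silhouette of the samples on a PC pair under the given labels."""
    pts = result.scores[:, [pcs[0] - 1, pcs[1] - 1]]
    return float(silhouette_score(pts, np.asarray(labels)))
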