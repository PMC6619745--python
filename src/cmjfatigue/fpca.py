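"""Penalised b-spline smoothing and multivariate functional PCA of
concentric force-time curves.

Each jump's concentric force curve (in bodyweight multiples) is linearly
time-normalised to [0, 1], smoothed with a cubic b-spline basis under a
second-derivative roughness penalty (lambda chosen by generalised
cross-validation), and the eight time-point curves of a sample are stacked
into one multivariate functional observation.  The fPCA eigenfunctions are
therefore vectors of eight functions, orthonormal under the concatenated
L2 inner product; per-slot score contributions support the heat-map style
hierarchical clustering of samples and of time points.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import linalg
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import BSpline

from .processing import ConcentricSegment, META_COLUMNS
from .synthetic import TIME_LABELS

logger = logging.getLogger(__name__)

DEFAULT_N_GRID = 101
DEFAULT_N_BASIS = 20
DEFAULT_LAMBDAS = tuple(np.logspace(-8, 2, 21))


# ---------------------------------------------------------------------------
# basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BSplineBasis:
    """B-spline basis of ``order`` k (default cubic, k=4) on [0, 1] with
    uniformly spaced interior knots and open (repeated) end knots."""

    n_basis: int = DEFAULT_N_BASIS
    order: int = 4

    def __post_init__(self) -> None:
        if self.order < 4:
            raise ValueError("basis order must be >= 4 (cubic or higher)")
        if self.n_basis < self.order:
            raise ValueError("n_basis must be >= order")

    @property
    def knots(self) -> np.ndarray:
        k = self.order
        interior = np.linspace(0.0, 1.0, self.n_basis - k + 2)[1:-1]
        return np.concatenate([np.zeros(k), interior, np.ones(k)])

    def design(self, x: np.ndarray) -> np.ndarray:
        """Evaluation matrix B with B[i, j] = B_j(x_i)."""
        x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        return BSpline.design_matrix(x, self.knots, self.order - 1, extrapolate=False).toarray()

    def _quad_matrix(self, deriv: int, n_points: int) -> np.ndarray:
        """Gauss-Legendre integral of (d^deriv B)(x) (d^deriv B)(x)^T over [0,1].

        The integrand is piecewise polynomial of degree 2*(order-1-deriv), so a
        fixed small rule per knot span is exact.
        """
        xg, wg = leggauss(n_points)
        knots = self.knots
        spans = np.unique(knots)
        out = np.zeros((self.n_basis, self.n_basis))
        eye = np.eye(self.n_basis)
        splines = [BSpline(knots, eye[j], self.order - 1) for j in range(self.n_basis)]
        dsplines = [s.derivative(deriv) if deriv else s for s in splines]
        for a, b in zip(spans[:-1], spans[1:]):
            x = 0.5 * (b - a) * xg + 0.5 * (a + b)
            vals = np.array([d(x) for d in dsplines])
            out += 0.5 * (b - a) * (vals * wg) @ vals.T
        return out

    def gram(self) -> np.ndarray:
        """Gram matrix G_ij = integral of B_i B_j (exact quadrature)."""
        return self._quad_matrix(0, self.order)

    def penalty(self) -> np.ndarray:
        """Roughness penalty P_ij = integral of B_i'' B_j'' (exact quadrature)."""
        return self._quad_matrix(2, max(self.order - 2, 2))

    def integrals(self) -> np.ndarray:
        """integral of each basis function; equals the Gram row sums because
        b-splines form a partition of unity."""
        return self.gram().sum(axis=1)


@dataclass
class FunctionalCurve:
    """A smoothed curve: basis + coefficients (+ the original duration, s)."""

    basis: BSplineBasis
    coefficients: np.ndarray
    lam: float
    duration_s: float | None = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.basis.design(x) @ self.coefficients


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def time_normalize(segment: ConcentricSegment, n_grid: int = DEFAULT_N_GRID) -> np.ndarray:
    """Concentric force (BW multiples) on a common grid over normalised time.

    Linear time rescaling by the segment's duration, then linear
    interpolation onto ``n_grid`` evenly spaced points in [0, 1].
    """
    if n_grid < 21:
        raise ValueError("n_grid must be >= 21")
    if segment.duration <= 0:
        raise ValueError("segment duration must be positive")
    s = segment.time / segment.duration
    grid = np.linspace(0.0, 1.0, n_grid)
    return np.interp(grid, s, segment.force / segment.bodyweight_n)


def _solver(basis: BSplineBasis, n_grid: int, lam: float):
    """Factorised penalised-least-squares solve for a fixed grid/basis/lambda."""
    grid = np.linspace(0.0, 1.0, n_grid)
    B = basis.design(grid)
    P = basis.penalty()
    A = B.T @ B + lam * P
    try:
        c, low = linalg.cho_factor(A)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            f"singular smoothing system (n_basis={basis.n_basis}); try fewer basis functions"
        ) from err
    return B, (c, low)


def fit_bspline(
    values: np.ndarray,
    n_basis: int = DEFAULT_N_BASIS,
    lam: float = 0.0,
    basis: BSplineBasis | None = None,
    duration_s: float | None = None,
) -> FunctionalCurve:
    """Penalised least-squares spline fit of curve values on the uniform grid.

    Minimises ||y - B c||^2 + lam * c' P c with P the integrated squared
    second derivative — the classic penalised smoothing objective, solved in
    closed form.
    """
    values = np.asarray(values, dtype=float)
    basis = basis or BSplineBasis(n_basis)
    if basis.n_basis > values.size:
        raise ValueError("n_basis must not exceed the number of grid points")
    B, fac = _solver(basis, values.size, lam)
    coefs = linalg.cho_solve(fac, B.T @ values)
    return FunctionalCurve(basis, coefs, lam, duration_s)


def gcv_score(values: np.ndarray, n_basis: int, lam: float) -> float:
    """Generalised cross-validation score n*RSS / (n - tr(H))^2."""
    values = np.asarray(values, dtype=float)
    n = values.size
    basis = BSplineBasis(n_basis)
    B, fac = _solver(basis, n, lam)
    coefs = linalg.cho_solve(fac, B.T @ values)
    rss = float(np.sum((values - B @ coefs) ** 2))
    tr_h = float(np.trace(linalg.cho_solve(fac, B.T @ B)))
    return n * rss / (n - tr_h) ** 2


def _gcv_lambdas(
    Y: np.ndarray, n_basis: int, lambdas: tuple[float, ...]
) -> np.ndarray:
    """Per-curve GCV-minimising lambda for many curves (rows of Y) at once;
    one factorisation per grid lambda, shared across curves."""
    lams = sorted(float(l) for l in lambdas)
    if any(l <= 0 for l in lams):
        raise ValueError("lambda grid must be positive")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[1]
    basis = BSplineBasis(n_basis)
    scores = np.empty((len(lams), Y.shape[0]))
    for i, lam in enumerate(lams):
        B, fac = _solver(basis, n, lam)
        coefs = linalg.cho_solve(fac, B.T @ Y.T)
        rss = np.sum((Y.T - B @ coefs) ** 2, axis=0)
        tr_h = float(np.trace(linalg.cho_solve(fac, B.T @ B)))
        scores[i] = n * rss / (n - tr_h) ** 2
    return np.asarray(lams)[np.argmin(scores, axis=0)]


def select_lambda_gcv(
    values: np.ndarray,
    n_basis: int = DEFAULT_N_BASIS,
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS,
) -> float:
    """The grid minimiser of the GCV score (smallest lambda wins ties)."""
    return float(_gcv_lambdas(np.atleast_2d(values), n_basis, lambdas)[0])


def smooth_curves(
    curve_matrix: np.ndarray,
    n_basis: int = DEFAULT_N_BASIS,
    lam: float | None = None,
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS,
) -> tuple[np.ndarray, float]:
    """Smooth many curves (rows) with a common lambda.

    When ``lam`` is None, GCV selects a lambda per curve and the median is
    applied to all curves so every sample shares the same smoothing level.
    Returns (coefficients (n_curves, n_basis), lambda used).
    """
    Y = np.atleast_2d(np.asarray(curve_matrix, dtype=float))
    if lam is None:
        lam = float(np.median(_gcv_lambdas(Y, n_basis, lambdas)))
    basis = BSplineBasis(n_basis)
    B, fac = _solver(basis, Y.shape[1], lam)
    coefs = linalg.cho_solve(fac, B.T @ Y.T).T
    return coefs, lam


# ---------------------------------------------------------------------------
# multivariate fPCA
# ---------------------------------------------------------------------------

@dataclass
class FPCAResult:
    """Multivariate fPCA decomposition.

    ``eigen_coefs[j, s]`` are the basis coefficients of PC j's slot-s
    function; eigenfunctions are orthonormal under the concatenated L2 inner
    product sum_s integral(f_s g_s).  ``scores[i, j]`` is the inner product
    of centred sample i with eigenfunction j.
    """

    basis: BSplineBasis
    slot_labels: tuple[str, ...]
    mean_coefs: np.ndarray        # (n_slots, n_basis)
    eigen_coefs: np.ndarray       # (k, n_slots, n_basis)
    scores: np.ndarray            # (n_samples, k)
    proportions: np.ndarray       # (k,)
    index: pd.DataFrame
    coefs_centred: np.ndarray = field(repr=False, default=None)  # (n, n_slots, n_basis)
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return self.eigen_coefs.shape[0]

    def evaluate(self, pc: int, slot: int, x: np.ndarray) -> np.ndarray:
        """Evaluate PC ``pc`` (1-based) in time-point slot ``slot`` at x."""
        return self.basis.design(x) @ self.eigen_coefs[pc - 1, slot]

    def slot_scores(self, pc: int) -> np.ndarray:
        """Per-time-point score contributions (n_samples, n_slots).

        Entry (i, s) is the inner product, restricted to slot s, of sample i's
        deviation from the *grand mean curve* (the average of the eight slot
        means) with the eigenfunction.  Centring on the grand mean rather than
        per slot keeps the mean fatigue time course visible in the heat map:
        a time point whose average curve deviates along this PC shows a
        coherent red/blue column.  Up to a per-slot constant shared by all
        samples, slot contributions sum to the full score.
        """
        G = self.basis.gram()
        grand = self.mean_coefs.mean(axis=0)
        dev = self.coefs_centred + (self.mean_coefs - grand)[None, :, :]
        return np.einsum("nsb,bc,sc->ns", dev, G, self.eigen_coefs[pc - 1])


def run_fpca(
    coefs: np.ndarray,
    basis: BSplineBasis,
    slot_labels: tuple[str, ...] = TIME_LABELS,
    index: pd.DataFrame | None = None,
    gram: np.ndarray | None = None,
) -> FPCAResult:
    """fPCA of stacked per-slot coefficient vectors.

    ``coefs`` has shape (n_samples, n_slots, n_basis): every sample carries
    one smoothed curve per measurement time point, all sharing ``basis``.
    The covariance of the centred coefficients is eigen-decomposed in the
    metric of the (block-diagonal) basis Gram matrix via its Cholesky
    factor, which makes the eigenfunctions orthonormal under the
    concatenated L2 inner product.  Sign convention: each PC is flipped so
    the integral of its mean slot function is positive.

    ``gram`` overrides the inner-product metric (default: the exact basis
    Gram matrix).  Passing the grid-quadrature Gram B'B/n recovers, with an
    interpolating basis and zero penalty, exactly the discrete PCA of the
    grid values — the identity used by the equivalence checks.
    """
    coefs = np.asarray(coefs, dtype=float)
    n, n_slots, m = coefs.shape
    if n_slots != len(slot_labels):
        raise ValueError("slot_labels length does not match coefficient slots")
    if index is None:
        index = pd.DataFrame({"sample": np.arange(n)})
    mean = coefs.mean(axis=0)
    centred = coefs - mean

    G = basis.gram() if gram is None else np.asarray(gram, dtype=float)
    L = linalg.cholesky(G, lower=True)          # G = L L'
    Y = (centred @ L).reshape(n, n_slots * m)   # slot-wise half-transform
    total_var = float(np.sum(Y ** 2) / max(n - 1, 1))
    if total_var < 1e-12:
        logger.warning("fPCA input has (near-)zero variance; proportions undefined")
        k = 1
        return FPCAResult(
            basis, tuple(slot_labels), mean,
            np.zeros((k, n_slots, m)), np.zeros((n, k)),
            np.full(k, np.nan), index, centred, degenerate=True,
        )

    U, sv, Vt = np.linalg.svd(Y, full_matrices=False)
    eigvals = sv ** 2 / (n - 1)
    keep = eigvals > max(eigvals[0] * 1e-12, 1e-15)
    k = int(keep.sum())
    V = Vt[:k].reshape(k, n_slots, m)
    # back-transform: eigenfunction coefficients b solve L' b = v per slot
    eigen = np.einsum("bc,ksc->ksb", np.linalg.inv(L).T, V)
    scores = Y @ Vt[:k].T
    proportions = eigvals[:k] / eigvals.sum()

    w = basis.integrals()
    flip = np.sign(np.einsum("ksb,b->k", eigen, w))
    flip[flip == 0] = 1.0
    eigen *= flip[:, None, None]
    scores *= flip[None, :]
    return FPCAResult(basis, tuple(slot_labels), mean, eigen, scores, proportions,
                      index.copy(), centred)


@dataclass
class PooledFPCAResult:
    """Univariate fPCA pooled over every (sample, time point) curve.

    All n_samples x n_slots curves enter one decomposition around the grand
    mean curve, so each cell of the score heat map gets its own scalar score
    and the mean fatigue time course stays visible in the score columns —
    the natural construction for clustering samples and time points.
    """

    basis: BSplineBasis
    slot_labels: tuple[str, ...]
    mean_coefs: np.ndarray       # (n_basis,) grand mean curve
    eigen_coefs: np.ndarray      # (k, n_basis), orthonormal under the Gram metric
    scores: np.ndarray           # (n_samples, n_slots, k)
    proportions: np.ndarray
    index: pd.DataFrame

    @property
    def n_components(self) -> int:
        return self.eigen_coefs.shape[0]

    def evaluate(self, pc: int, x: np.ndarray) -> np.ndarray:
        return self.basis.design(x) @ self.eigen_coefs[pc - 1]

    def slot_scores(self, pc: int) -> np.ndarray:
        """Score matrix (n_samples, n_slots) for one PC."""
        return self.scores[:, :, pc - 1]


def run_pooled_fpca(
    coefs: np.ndarray,
    basis: BSplineBasis,
    slot_labels: tuple[str, ...] = TIME_LABELS,
    index: pd.DataFrame | None = None,
    n_components: int = 8,
) -> PooledFPCAResult:
    """Univariate fPCA over the pooled set of per-time-point curves.

    ``coefs`` has shape (n_samples, n_slots, n_basis) as in :func:`run_fpca`;
    here every curve is treated as one functional observation, centred on the
    grand mean.  Eigenfunctions are orthonormal in L2; the sign convention
    makes each eigenfunction's integral positive.
    """
    coefs = np.asarray(coefs, dtype=float)
    n, n_slots, m = coefs.shape
    if index is None:
        index = pd.DataFrame({"sample": np.arange(n)})
    C = coefs.reshape(n * n_slots, m)
    mean = C.mean(axis=0)
    G = basis.gram()
    L = linalg.cholesky(G, lower=True)
    Y = (C - mean) @ L
    U, sv, Vt = np.linalg.svd(Y, full_matrices=False)
    total = float(np.sum(sv ** 2))
    if total < 1e-12:
        raise ValueError("pooled curves have (near-)zero variance")
    k = min(n_components, (sv ** 2 > sv[0] ** 2 * 1e-12).sum())
    eigen = linalg.solve_triangular(L.T, Vt[:k].T).T        # (k, m)
    w = basis.integrals()
    flip = np.sign(eigen @ w)
    flip[flip == 0] = 1.0
    eigen *= flip[:, None]
    scores = (Y @ Vt[:k].T * flip[None, :]).reshape(n, n_slots, k)
    return PooledFPCAResult(
        basis, tuple(slot_labels), mean, eigen, scores,
        (sv[:k] ** 2) / total, index.copy(),
    )


# ---------------------------------------------------------------------------
# curve assembly and clustering
# ---------------------------------------------------------------------------

def normalized_curve_table(
    segments: list[ConcentricSegment], n_grid: int = DEFAULT_N_GRID
) -> pd.DataFrame:
    """Long table of time-normalised curves: meta columns + g0..g{n_grid-1}."""
    rows = []
    for seg in segments:
        row = {k: seg.meta.get(k) for k in META_COLUMNS}
        row["duration_s"] = seg.duration
        row.update({f"g{i}": v for i, v in enumerate(time_normalize(seg, n_grid))})
        rows.append(row)
    return pd.DataFrame(rows)


def stack_curves(
    curves: pd.DataFrame,
    slot_labels: tuple[str, ...] = TIME_LABELS,
    n_basis: int = DEFAULT_N_BASIS,
    lam: float | None = None,
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS,
) -> tuple[np.ndarray, pd.DataFrame, BSplineBasis, float]:
    """Smooth a curve table and stack it per sample over the time-point slots.

    Samples (athlete, workload, jump) missing any slot are dropped with a
    logged count.  Returns (coefs (n, n_slots, n_basis), index, basis, lambda).
    """
    gcols = [c for c in curves.columns if c.startswith("g") and c[1:].isdigit()]
    gcols = sorted(gcols, key=lambda c: int(c[1:]))
    all_coefs, lam_used = smooth_curves(
        curves[gcols].to_numpy(dtype=float), n_basis=n_basis, lam=lam, lambdas=lambdas
    )
    df = curves[["athlete_id", "workload", "jump", "time_point"]].copy()
    df["row"] = np.arange(len(df))
    piv = df.pivot_table(
        index=["athlete_id", "workload", "jump"], columns="time_point",
        values="row", aggfunc="first", sort=False,
    )
    missing_slots = [t for t in slot_labels if t not in piv.columns]
    if missing_slots:
        raise ValueError(f"curve table lacks time points {missing_slots}")
    piv = piv[list(slot_labels)]
    complete = piv.dropna()
    if len(complete) < len(piv):
        logger.info("stack_curves dropped %d samples with incomplete curve vectors",
                    len(piv) - len(complete))
    if complete.empty:
        raise ValueError("no samples with a complete set of time-point curves")
    rows = complete.to_numpy(dtype=int)
    coefs = all_coefs[rows]                       # (n, n_slots, n_basis)
    return coefs, complete.index.to_frame(index=False), BSplineBasis(n_basis), lam_used


@dataclass
class ScoreClustering:
    """Hierarchical clustering of per-slot fPCA scores (samples and slots)."""

    pc: int
    matrix: np.ndarray            # (n_samples, n_slots) slot scores
    sample_linkage: np.ndarray
    time_linkage: np.ndarray
    sample_clusters: np.ndarray   # flat labels at the requested cut
    time_clusters: np.ndarray
    slot_labels: tuple[str, ...]


def cluster_scores(
    result: FPCAResult | PooledFPCAResult,
    pc: int = 1,
    n_sample_clusters: int = 3,
    n_time_clusters: int = 3,
    method: str = "ward",
) -> ScoreClustering:
    """Agglomerative (default Ward/Euclidean) clustering of one PC's per-
    time-point scores: samples as rows, time points as columns, as in the
    score heat map.  Accepts either the multivariate decomposition (slot-
    restricted contributions) or the pooled one (per-curve scores)."""
    M = result.slot_scores(pc)
    n, s = M.shape
    sample_link = (
        linkage(M, method=method) if n > 1 else np.empty((0, 4))
    )
    time_link = linkage(M.T, method=method) if s > 1 else np.empty((0, 4))
    sample_clusters = (
        fcluster(sample_link, t=min(n_sample_clusters, n), criterion="maxclust")
        if n > 1 else np.ones(1, dtype=int)
    )
    time_clusters = (
        fcluster(time_link, t=min(n_time_clusters, s), criterion="maxclust")
        if s > 1 else np.ones(1, dtype=int)
    )
    return ScoreClustering(pc, M, sample_link, time_link, sample_clusters,
                           time_clusters, result.slot_labels)
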