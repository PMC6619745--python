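"""Random-intercept mixed-effects prediction of relative peak force.

Eight model configurations predict each jump's relative peak concentric
force (BW multiples) at 6 h (metabolic horizon) or 48 h (neuromuscular
horizon) post-training from the first two PC scores of either the discrete
stratified PCA or the functional PCA, computed from either all eight
measurement time points ("baseline") or only the practically obtainable
window pre-, immediately post- and 0.5 h post-training ("practical").
Every model carries an athlete random intercept; estimation is maximum
likelihood (not REML) by profiling the fixed effects and residual variance
over the variance ratio.  Validation is leave-one-athlete-out
cross-validation with fixed-effects-only prediction for the held-out
athlete, pooled into an MSE; fit quality is the squared correlation between
observed and conditional fitted values; configurations are compared with
likelihood-ratio tests (with an explicit warning when the pair is not
nested, as when fPCA scores replace PCA scores).
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fpca import run_fpca, stack_curves, DEFAULT_LAMBDAS, DEFAULT_N_BASIS
from .pca import build_matrix, run_pca
from .processing import FEATURE_COLUMNS
from .synthetic import PRE, TIME_LABELS

logger = logging.getLogger(__name__)

#: the "practical" information window: measurements up to 0.5 h post-training
PRACTICAL_WINDOW = (PRE, "0", "0.5")

SAMPLE_KEYS = ["athlete_id", "workload", "jump"]


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration (a row of the 8-model design)."""

    horizon: str            # "6" or "48" — time point of the response
    source: str             # "pca" | "fpca" — where PC1/PC2 scores come from
    window: str             # "baseline" (all time points) | "practical"
    number: int = 0

    def __post_init__(self) -> None:
        if self.source not in ("pca", "fpca"):
            raise ValueError(f"unknown score source {self.source!r}")
        if self.window not in ("baseline", "practical"):
            raise ValueError(f"unknown window {self.window!r}")

    @property
    def name(self) -> str:
        src = "fPCA" if self.source == "fpca" else "PCA"
        return f"{self.horizon} h {src} {self.window.capitalize()}"

    @property
    def time_labels(self) -> tuple[str, ...]:
        return TIME_LABELS if self.window == "baseline" else PRACTICAL_WINDOW


#: the eight configurations, numbered as in the study design
DEFAULT_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec("6", "fpca", "baseline", 1),
    ModelSpec("6", "pca", "baseline", 2),
    ModelSpec("6", "fpca", "practical", 3),
    ModelSpec("6", "pca", "practical", 4),
    ModelSpec("48", "fpca", "baseline", 5),
    ModelSpec("48", "pca", "baseline", 6),
    ModelSpec("48", "fpca", "practical", 7),
    ModelSpec("48", "pca", "practical", 8),
)


# ---------------------------------------------------------------------------
# profiled-ML random-intercept fit
# ---------------------------------------------------------------------------

@dataclass
class LMEFit:
    """ML fit of y = X beta + Z b + e with b ~ N(0, s2_b) per group."""

    beta: np.ndarray
    se_beta: np.ndarray
    sigma2_b: float
    sigma2_e: float
    loglik: float
    fitted_marginal: np.ndarray      # X beta
    fitted: np.ndarray               # X beta + BLUP intercepts
    converged: bool
    y: np.ndarray = field(repr=False, default=None)
    groups: np.ndarray = field(repr=False, default=None)
    predictor_names: tuple[str, ...] | None = None

    @property
    def n_params(self) -> int:
        """Fixed-effect count (the df currency of the likelihood-ratio test)."""
        return len(self.beta)


def _profile_loglik(psi: float, y: np.ndarray, X: np.ndarray, idx: list[np.ndarray]):
    """Profiled ML log-likelihood at variance ratio psi = s2_b / s2_e.

    For the random-intercept model, V = s2_e (I + psi J) blockwise, and
    V^{-1} has the closed Woodbury form; beta and s2_e are profiled out.
    """
    n = y.size
    XtWX = np.zeros((X.shape[1], X.shape[1]))
    XtWy = np.zeros(X.shape[1])
    logdet = 0.0
    for g in idx:
        ng = g.size
        c = psi / (1.0 + psi * ng)
        Xg, yg = X[g], y[g]
        XtWX += Xg.T @ Xg - c * np.outer(Xg.sum(0), Xg.sum(0))
        XtWy += Xg.T @ yg - c * Xg.sum(0) * yg.sum()
        logdet += np.log1p(psi * ng)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = 0.0
    for g in idx:
        ng = g.size
        c = psi / (1.0 + psi * ng)
        r = y[g] - X[g] @ beta
        rss += r @ r - c * r.sum() ** 2
    s2e = rss / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * s2e) + n + logdet)
    return ll, beta, s2e, XtWX


def fit_lme(
    y: np.ndarray,
    X: np.ndarray,
    groups: Sequence,
    predictor_names: tuple[str, ...] | None = None,
) -> LMEFit:
    """Maximum-likelihood fit of the random-intercept model.

    ``X`` must contain the intercept column and be full column rank.  The
    marginal Gaussian likelihood is maximised by a bounded 1-D search over
    log(psi), psi = sigma2_b / sigma2_e, with beta and sigma2_e profiled out
    in closed form.  Returns ML (not REML) estimates; standard errors are
    the plug-in GLS ones.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    groups = np.asarray(groups)
    if y.size != len(X) or y.size != groups.size:
        raise ValueError("y, X and groups must have matching lengths")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    labels, inv = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    idx = [np.nonzero(inv == k)[0] for k in range(len(labels))]
    converged = True
    if all(g.size == 1 for g in idx):
        # one observation per group: s2_b and s2_e are not separately
        # identifiable; report the boundary fit, flagged
        converged = False

    lo, hi = -15.0, 15.0
    res = optimize.minimize_scalar(
        lambda t: -_profile_loglik(np.exp(t), y, X, idx)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    t_hat = float(res.x)
    # the boundary psi -> 0 (pure OLS) is not interior to the search; take it
    # when it beats the interior optimum
    ll_hat = _profile_loglik(np.exp(t_hat), y, X, idx)[0]
    ll_zero = _profile_loglik(0.0, y, X, idx)[0]
    psi = 0.0 if ll_zero >= ll_hat else np.exp(t_hat)
    if t_hat > hi - 1e-6:
        converged = False
    ll, beta, s2e, XtWX = _profile_loglik(psi, y, X, idx)
    s2b = psi * s2e
    cov = s2e * np.linalg.inv(XtWX)
    fitted_marg = X @ beta
    # BLUP random intercepts for the conditional fit
    fitted = fitted_marg.copy()
    for g in idx:
        ng = g.size
        shrink = s2b * ng / (s2b * ng + s2e) if s2b > 0 else 0.0
        fitted[g] += shrink * float(np.mean(y[g] - fitted_marg[g]))
    return LMEFit(
        beta=beta, se_beta=np.sqrt(np.diag(cov)), sigma2_b=s2b, sigma2_e=s2e,
        loglik=float(ll), fitted_marginal=fitted_marg, fitted=fitted,
        converged=converged, y=y, groups=groups, predictor_names=predictor_names,
    )


@dataclass
class LoocvResult:
    mse: float
    n_folds: int
    fold_mse: dict
    skipped: list


def loocv(y: np.ndarray, X: np.ndarray, groups: Sequence) -> LoocvResult:
    """Leave-one-athlete-out cross-validation.

    Each fold refits on the remaining athletes and predicts the held-out
    athlete's rows with fixed effects only (an unseen athlete has no
    estimable intercept); squared errors are pooled over all held-out rows.
    Degenerate folds (rank-deficient design) are skipped and logged.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 3:
        raise ValueError("leave-one-out over groups needs at least 3 groups")
    sq, fold_mse, skipped = [], {}, []
    for lab in labels:
        held = groups == lab
        try:
            fit = fit_lme(y[~held], X[~held], groups[~held])
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("LOOCV fold %r skipped: %s", lab, err)
            skipped.append(str(lab))
            continue
        err2 = (y[held] - X[held] @ fit.beta) ** 2
        sq.extend(err2.tolist())
        fold_mse[str(lab)] = float(np.mean(err2))
    return LoocvResult(float(np.mean(sq)), len(fold_mse), fold_mse, skipped)


def r_squared(fit: LMEFit, y: np.ndarray | None = None) -> float:
    """Squared Pearson correlation between observed and conditional fitted
    values (fixed effects + predicted random intercepts).  Returns NaN for a
    response with zero variance."""
    y = fit.y if y is None else np.asarray(y, dtype=float)
    if np.std(y) == 0 or np.std(fit.fitted) == 0:
        warnings.warn("R^2 undefined: zero variance in observed or fitted values")
        return float("nan")
    return float(np.corrcoef(y, fit.fitted)[0, 1] ** 2)


def pseudo_r_squared(fit: LMEFit) -> tuple[float, float]:
    """(marginal, conditional) variance-decomposition pseudo-R^2: the shares
    of variance explained by fixed effects alone and by fixed + random."""
    var_f = float(np.var(fit.fitted_marginal))
    denom = var_f + fit.sigma2_b + fit.sigma2_e
    return var_f / denom, (var_f + fit.sigma2_b) / denom


@dataclass
class LRTResult:
    lr: float
    df: int
    p_value: float
    warning: str | None = None


def likelihood_ratio_test(fit_a: LMEFit, fit_b: LMEFit) -> LRTResult:
    """Likelihood-ratio comparison of two fits of the same response.

    LR = 2 |ll_a - ll_b|; the chi-square reference uses df = difference in
    fixed-effect counts.  Equal-size predictor sets that are not identical
    are non-nested: the raw LR is still reported (df 0, p = NaN) with a
    warning attached, since the chi-square calibration does not apply.
    """
    if fit_a.y.size != fit_b.y.size:
        raise ValueError("fits have different response lengths")
    if not np.allclose(fit_a.y, fit_b.y):
        raise ValueError("fits are not of the same response vector")
    lr = 2.0 * abs(fit_a.loglik - fit_b.loglik)
    df = abs(fit_a.n_params - fit_b.n_params)
    warning = None
    na, nb = fit_a.predictor_names, fit_b.predictor_names
    nested = na is not None and nb is not None and (set(na) <= set(nb) or set(nb) <= set(na))
    if not nested:
        warning = (
            "models are not nested; the likelihood ratio is descriptive and "
            "the chi-square p-value does not apply"
        )
    if df == 0:
        p = float("nan") if not nested else 1.0 if lr == 0 else float("nan")
    else:
        p = float(stats.chi2.sf(lr, df))
    return LRTResult(float(lr), df, p, warning)


# ---------------------------------------------------------------------------
# model inputs from the pipeline tables
# ---------------------------------------------------------------------------

def compute_scores(
    features: pd.DataFrame,
    curves: pd.DataFrame | None,
    spec: ModelSpec,
    n_basis: int = DEFAULT_N_BASIS,
    lam: float | None = None,
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS,
    baseline_labels: tuple[str, ...] = TIME_LABELS,
) -> pd.DataFrame:
    """PC1/PC2 scores per sample for one model spec's information window.

    The PCA or fPCA is re-run on the restricted window (4 features x 3 time
    points = 12 variables for the practical window), not projected from the
    full-window components: restricting the window changes the components
    themselves.
    """
    labels = baseline_labels if spec.window == "baseline" else PRACTICAL_WINDOW
    if spec.source == "pca":
        mat = build_matrix(features, time_labels=labels)
        res = run_pca(mat)
        out = mat.index.copy()
        out["PC1"], out["PC2"] = res.scores[:, 0], res.scores[:, 1]
        return out
    if curves is None:
        raise ValueError("fPCA-based specs need the curve table")
    sub = curves[curves["time_point"].isin(labels)]
    coefs, index, basis, _ = stack_curves(
        sub, slot_labels=labels, n_basis=n_basis, lam=lam, lambdas=lambdas
    )
    res = run_fpca(coefs, basis, slot_labels=labels, index=index)
    out = index.copy()
    out["PC1"], out["PC2"] = res.scores[:, 0], res.scores[:, 1]
    return out


def build_inputs(
    features: pd.DataFrame, scores: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """(y, X, groups, index) for one spec: the response is each sample's
    rel_peak_force at the horizon time point; predictors are an intercept and
    the sample's PC1/PC2 scores.  Samples missing the horizon measurement
    are dropped with a logged count."""
    resp = features[features["time_point"] == spec.horizon]
    resp = resp.groupby(SAMPLE_KEYS, as_index=False)["rel_peak_force"].mean()
    merged = scores.merge(resp, on=SAMPLE_KEYS, how="left")
    missing = merged["rel_peak_force"].isna()
    if missing.any():
        logger.info("dropped %d samples lacking the %s h response",
                    int(missing.sum()), spec.horizon)
    merged = merged[~missing].reset_index(drop=True)
    y = merged["rel_peak_force"].to_numpy()
    X = np.column_stack([np.ones(len(merged)), merged["PC1"], merged["PC2"]])
    return y, X, merged["athlete_id"].to_numpy(), merged[SAMPLE_KEYS]


# ---------------------------------------------------------------------------
# the full 8-model report
# ---------------------------------------------------------------------------

#: comparisons mirroring the study's likelihood-ratio table
LRT_PAIRS = (
    ("6 h fPCA Baseline", "6 h PCA Baseline"),
    ("48 h fPCA Baseline", "48 h PCA Baseline"),
    ("6 h PCA Practical", "6 h fPCA Practical"),
    ("48 h PCA Practical", "48 h fPCA Practical"),
    ("6 h fPCA Baseline", "6 h fPCA Practical"),
    ("48 h fPCA Baseline", "48 h fPCA Practical"),
)


@dataclass
class ModelReport:
    """Fitted models, cross-validated errors and pairwise comparisons."""

    fit_table: pd.DataFrame      # per spec: name, cv MSE, R2, loglik, ...
    lrt_table: pd.DataFrame      # pairwise LR, delta MSE, p, warning
    fits: dict = field(default_factory=dict, repr=False)

    def to_json(self, path) -> None:
        payload = {
            "fit_table": self.fit_table.to_dict(orient="records"),
            "lrt_table": self.lrt_table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, allow_nan=True)

    @classmethod
    def from_json(cls, path) -> "ModelReport":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            pd.DataFrame(payload["fit_table"]),
            pd.DataFrame(payload["lrt_table"]),
        )


def run_all_models(
    features: pd.DataFrame,
    curves: pd.DataFrame | None,
    specs: Sequence[ModelSpec] = DEFAULT_SPECS,
    n_basis: int = DEFAULT_N_BASIS,
    lam: float | None = None,
    baseline_labels: tuple[str, ...] = TIME_LABELS,
) -> ModelReport:
    """Fit every spec, cross-validate it, and build the comparison tables."""
    rows, fits, failures = [], {}, {}
    for spec in specs:
        try:
            scores = compute_scores(features, curves, spec, n_basis=n_basis, lam=lam,
                                    baseline_labels=baseline_labels)
            y, X, groups, _ = build_inputs(features, scores, spec)
            names = ("intercept", f"{spec.source}:{spec.window}:PC1",
                     f"{spec.source}:{spec.window}:PC2")
            fit = fit_lme(y, X, groups, predictor_names=names)
            cv = loocv(y, X, groups)
            r2m, r2c = pseudo_r_squared(fit)
            fits[spec.name] = (fit, cv)
            rows.append({
                "model": spec.number, "name": spec.name, "horizon_h": spec.horizon,
                "source": spec.source, "window": spec.window, "n": len(y),
                "cv_mse": cv.mse, "r2": r_squared(fit), "loglik": fit.loglik,
                "r2_marginal": r2m, "r2_conditional": r2c,
                "sigma2_b": fit.sigma2_b, "sigma2_e": fit.sigma2_e,
                "converged": fit.converged, "cv_folds": cv.n_folds,
            })
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.error("model %s failed: %s", spec.name, err)
            failures[spec.name] = str(err)
            rows.append({"model": spec.number, "name": spec.name, "error": str(err)})
    fit_table = pd.DataFrame(rows)

    lrt_rows = []
    for name_a, name_b in LRT_PAIRS:
        if name_a not in fits or name_b not in fits:
            continue
        (fit_a, cv_a), (fit_b, cv_b) = fits[name_a], fits[name_b]
        try:
            lrt = likelihood_ratio_test(fit_a, fit_b)
        except ValueError as err:
            logger.warning("LRT %s vs %s skipped: %s", name_a, name_b, err)
            continue
        lrt_rows.append({
            "comparison": f"{name_a} vs {name_b}",
            "likelihood_ratio": lrt.lr, "df": lrt.df, "p_value": lrt.p_value,
            "delta_cv_mse": abs(cv_a.mse - cv_b.mse),
            "warning": lrt.warning or "",
        })
    return ModelReport(fit_table, pd.DataFrame(lrt_rows), fits)
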