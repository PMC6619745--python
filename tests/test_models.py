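"""Random-intercept ML estimation, leave-one-athlete-out cross-validation,
fit statistics and likelihood-ratio comparisons."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, multivariate_normal

from cmjfatigue import (
    DEFAULT_SPECS, ModelSpec, NoiseParams, build_inputs, compute_scores,
    draw_athletes, features_table, fit_lme, likelihood_ratio_test, loocv,
    pseudo_r_squared, r_squared, run_all_models, simulate_study,
)
from cmjfatigue.fpca import normalized_curve_table
from cmjfatigue.models import ModelReport
from cmjfatigue.processing import concentric_segments
from cmjfatigue.synthetic import StudyDesign


def _sim_lme(rng, n_groups=10, per_group=15, beta=(1.0, 0.5, -0.3),
             s_b=0.2, s_e=0.1):
    groups = np.repeat(np.arange(n_groups), per_group)
    X = np.column_stack([np.ones(groups.size),
                         rng.normal(size=(groups.size, len(beta) - 1))])
    b = rng.normal(0, s_b, n_groups)
    y = X @ beta + b[groups] + rng.normal(0, s_e, groups.size)
    return y, X, groups


def _grid_loglik(y, X, groups, s2b, s2e):
    """Direct marginal Gaussian log-likelihood (independent oracle)."""
    same = groups[:, None] == groups[None, :]
    V = s2e * np.eye(y.size) + s2b * same
    beta = np.linalg.solve(X.T @ np.linalg.solve(V, X),
                           X.T @ np.linalg.solve(V, y))
    return multivariate_normal.logpdf(y, X @ beta, V), beta


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def test_profiled_ml_matches_brute_force_grid():
    """Balanced toy data: the profiled optimiser's log-likelihood meets a
    two-stage brute-force grid over (s2_b, s2_e) to 1e-4 (and beats it)."""
    rng = np.random.default_rng(1)
    y, X, g = _sim_lme(rng, n_groups=3, per_group=4, beta=(1.0, 0.5),
                       s_b=0.4, s_e=0.3)
    fit = fit_lme(y, X, g)
    # coarse grid, then refined around the coarse optimum
    grid_b = np.linspace(1e-6, 1.0, 60)
    grid_e = np.linspace(0.01, 1.0, 60)
    best = max(((s2b, s2e) for s2b in grid_b for s2e in grid_e),
               key=lambda p: _grid_loglik(y, X, g, *p)[0])
    grid_b = np.linspace(max(best[0] - 0.02, 1e-8), best[0] + 0.02, 60)
    grid_e = np.linspace(max(best[1] - 0.02, 1e-4), best[1] + 0.02, 60)
    best = max(((s2b, s2e) for s2b in grid_b for s2e in grid_e),
               key=lambda p: _grid_loglik(y, X, g, *p)[0])
    ll_grid, beta_grid = _grid_loglik(y, X, g, *best)
    assert fit.loglik >= ll_grid - 1e-10
    assert abs(fit.loglik - ll_grid) < 1e-4
    assert np.allclose(fit.beta, beta_grid, atol=1e-3)
    assert abs(fit.sigma2_b - best[0]) < 1e-3
    assert abs(fit.sigma2_e - best[1]) < 1e-3


def test_lme_matches_statsmodels_ml():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(2)
    y, X, g = _sim_lme(rng)
    fit = fit_lme(y, X, g)
    ref = sm.MixedLM(y, X, groups=g).fit(reml=False)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)
    assert np.allclose(fit.beta, ref.fe_params, atol=1e-5)


def test_zero_between_variance_reduces_to_ols():
    rng = np.random.default_rng(3)
    groups = np.repeat(np.arange(5), 10)
    X = np.column_stack([np.ones(50), rng.normal(size=50)])
    y = X @ [2.0, 1.0] + rng.normal(0, 0.3, 50)   # no group effect at all
    fit = fit_lme(y, X, groups)
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    if fit.sigma2_b < 1e-10:                       # boundary solution
        assert np.allclose(fit.beta, ols, atol=1e-8)


def test_sigma2b_zero_recovery_monte_carlo():
    """Simulated without athlete effects, the estimate lands at ~0 and the
    fixed effects stay within 2 SEs of truth in >= 90% of 100 replicates."""
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        y, X, g = _sim_lme(rng, beta=(1.0, 0.5), s_b=0.0, s_e=0.01)
        fit = fit_lme(y, X, g)
        ok = fit.sigma2_b < 1e-4
        ok &= abs(fit.beta[1] - 0.5) <= 2 * fit.se_beta[1]
        hits += ok
    assert hits >= 90


def test_wald_coverage_at_study_scale():
    """95% Wald intervals for the slopes cover truth in [88%, 99%] of 200
    replicates at the study's size (150 rows, 10 athletes)."""
    covered, total = 0, 0
    for rep in range(200):
        rng = np.random.default_rng(5000 + rep)
        y, X, g = _sim_lme(rng, n_groups=10, per_group=15, s_b=0.2, s_e=0.1)
        fit = fit_lme(y, X, g)
        for j, truth in ((1, 0.5), (2, -0.3)):
            covered += abs(fit.beta[j] - truth) <= 1.96 * fit.se_beta[j]
            total += 1
    rate = covered / total
    assert 0.88 <= rate <= 0.99


def test_one_observation_per_group_flags_identifiability():
    rng = np.random.default_rng(4)
    groups = np.arange(12)
    X = np.column_stack([np.ones(12), rng.normal(size=12)])
    y = X @ [1.0, 0.5] + rng.normal(0, 0.2, 12)
    fit = fit_lme(y, X, groups)
    assert not fit.converged


def test_rank_deficient_design_is_an_error():
    rng = np.random.default_rng(5)
    groups = np.repeat(np.arange(4), 5)
    x = rng.normal(size=20)
    X = np.column_stack([np.ones(20), x, 2 * x])
    with pytest.raises(ValueError, match="rank"):
        fit_lme(rng.normal(size=20), X, groups)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_loocv_perfect_linear_data_has_vanishing_mse():
    groups = np.repeat(np.arange(5), 6)
    x = np.linspace(-1, 1, 30)
    X = np.column_stack([np.ones(30), x])
    y = X @ [1.0, 2.0]
    res = loocv(y, X, groups)
    assert res.mse < 1e-10
    assert res.n_folds == 5


def test_loocv_folds_equal_athletes(study_features):
    spec = ModelSpec("6", "pca", "baseline")
    scores = compute_scores(study_features, None, spec)
    y, X, g, _ = build_inputs(study_features, scores, spec)
    res = loocv(y, X, g)
    assert res.n_folds == 10


def test_loocv_invariant_to_group_relabelling():
    rng = np.random.default_rng(6)
    y, X, g = _sim_lme(rng, n_groups=6, per_group=5)
    relabel = {k: f"athlete-{9 - k}" for k in range(6)}
    a = loocv(y, X, g)
    b = loocv(y, X, np.array([relabel[k] for k in g]))
    assert a.mse == pytest.approx(b.mse, rel=1e-6)


def test_practical_never_beats_baseline_on_average(replicate_tables):
    """Restricting scores to the pre/post/0.5 h window cannot help: the
    practical model's LOOCV MSE >= the baseline model's in >= 80% of
    replicates (6 h horizon, PCA scores)."""
    wins = 0
    for feats, _ in replicate_tables:
        mses = {}
        for window in ("baseline", "practical"):
            spec = ModelSpec("6", "pca", window)
            scores = compute_scores(feats, None, spec)
            y, X, g, _ = build_inputs(feats, scores, spec)
            mses[window] = loocv(y, X, g).mse
        wins += mses["practical"] >= mses["baseline"]
    assert wins >= 0.8 * len(replicate_tables)


# ---------------------------------------------------------------------------
# fit statistics and comparisons
# ---------------------------------------------------------------------------

def test_r_squared_limits():
    rng = np.random.default_rng(7)
    y, X, g = _sim_lme(rng)
    fit = fit_lme(y, X, g)
    perfect = fit_lme(X @ [1.0, 0.5, -0.3] + np.repeat(rng.normal(0, 1e-8, 10), 15),
                      X, g)
    assert r_squared(perfect) > 0.999999
    # uncorrelated predictors at large n -> R^2 near zero
    rng = np.random.default_rng(8)
    groups = np.repeat(np.arange(10), 200)
    X2 = np.column_stack([np.ones(2000), rng.normal(size=2000)])
    y2 = rng.normal(size=2000)
    weak = fit_lme(y2, X2, groups)
    assert r_squared(weak) < 0.01
    marg, cond = pseudo_r_squared(fit)
    assert 0.0 <= marg <= cond <= 1.0


def test_r_squared_undefined_for_constant_response():
    groups = np.repeat(np.arange(3), 4)
    X = np.column_stack([np.ones(12), np.linspace(0, 1, 12)])
    fit = fit_lme(np.linspace(0, 1, 12), X, groups)
    fit.y = np.full(12, 3.14)
    with pytest.warns(UserWarning):
        assert np.isnan(r_squared(fit))


def test_lrt_identical_models():
    rng = np.random.default_rng(9)
    y, X, g = _sim_lme(rng)
    fit = fit_lme(y, X, g, predictor_names=("i", "a", "b"))
    res = likelihood_ratio_test(fit, fit)
    assert res.lr == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_lrt_chi_square_oracle():
    """Known likelihoods ll=-10 vs -12 with one extra parameter: LR=4 and
    p = chi2_1 tail at 4 (~0.0455)."""
    rng = np.random.default_rng(10)
    y, X, g = _sim_lme(rng)
    full = fit_lme(y, X, g, predictor_names=("i", "a", "b"))
    reduced = fit_lme(y, X[:, :2], g, predictor_names=("i", "a"))
    full.loglik, reduced.loglik = -10.0, -12.0
    res = likelihood_ratio_test(full, reduced)
    assert res.lr == pytest.approx(4.0)
    assert res.df == 1
    assert res.p_value == pytest.approx(chi2.sf(4.0, 1), abs=1e-12)
    assert res.p_value == pytest.approx(0.0455, abs=5e-4)
    assert res.warning is None


def test_lrt_non_nested_pair_is_flagged():
    rng = np.random.default_rng(11)
    y, X, g = _sim_lme(rng)
    a = fit_lme(y, X, g, predictor_names=("i", "pca:PC1", "pca:PC2"))
    b = fit_lme(y, X + 0.1, g, predictor_names=("i", "fpca:PC1", "fpca:PC2"))
    res = likelihood_ratio_test(a, b)
    assert res.df == 0
    assert np.isnan(res.p_value)
    assert "not nested" in res.warning


def test_lrt_requires_same_response():
    rng = np.random.default_rng(12)
    y, X, g = _sim_lme(rng)
    fit = fit_lme(y, X, g)
    other = fit_lme(y[:-15], X[:-15], g[:-15])
    with pytest.raises(ValueError):
        likelihood_ratio_test(fit, other)
    shifted = fit_lme(y + 1.0, X, g)
    with pytest.raises(ValueError, match="same response"):
        likelihood_ratio_test(fit, shifted)


# ---------------------------------------------------------------------------
# the 8-model report
# ---------------------------------------------------------------------------

def test_window_sizes_of_design_matrices(study_features):
    base = compute_scores(study_features, None, ModelSpec("6", "pca", "baseline"))
    prac = compute_scores(study_features, None, ModelSpec("6", "pca", "practical"))
    assert {"PC1", "PC2"} <= set(base.columns)
    # the practical window re-runs PCA on 4 features x 3 time points
    from cmjfatigue import build_matrix
    assert build_matrix(study_features).shape[1] == 32
    assert build_matrix(
        study_features, time_labels=("PRE", "0", "0.5")).shape[1] == 12
    assert len(prac) == len(base) == 150


def test_missing_horizon_drops_samples_from_that_model_only(study_features):
    feats = study_features[
        ~((study_features.athlete_id == "A02") & (study_features.jump == 3)
          & (study_features.time_point == "48"))
    ]
    # practical-window scores do not touch the 48 h cells, so the sample is
    # lost only where its response is missing
    spec48 = ModelSpec("48", "pca", "practical")
    spec6 = ModelSpec("6", "pca", "practical")
    s48 = compute_scores(feats, None, spec48)
    s6 = compute_scores(feats, None, spec6)
    y48, *_ = build_inputs(feats, s48, spec48)
    y6, *_ = build_inputs(feats, s6, spec6)
    assert len(y6) == 150
    assert len(y48) == 147      # A02's jump 3 under each of the 3 workloads


def test_run_all_fits_eight_models_and_round_trips(study_features, study_curves, tmp_path):
    report = run_all_models(study_features, study_curves)
    assert len(report.fit_table) == 8
    assert set(report.fit_table.model) == set(range(1, 9))
    assert (report.fit_table.cv_mse > 0).all()
    assert (report.fit_table.r2 <= 1).all()
    assert len(report.lrt_table) == 6
    non_nested = report.lrt_table.comparison.str.contains("fPCA Baseline vs.*PCA Baseline")
    assert report.lrt_table.warning.str.contains("not nested").any()

    path = tmp_path / "report.json"
    report.to_json(path)
    back = ModelReport.from_json(path)
    pd.testing.assert_frame_equal(
        back.fit_table, report.fit_table.reset_index(drop=True), check_dtype=False
    )
    pd.testing.assert_frame_equal(
        back.lrt_table, report.lrt_table.reset_index(drop=True), check_dtype=False
    )


def test_noise_free_cohort_fits_nearly_perfectly():
    """With no jump-to-jump noise and uniform susceptibility, the generative
    link from scores to the response is deterministic: all R^2 > 0.99."""
    design = StudyDesign(jumps_per_set=2)
    root = np.random.default_rng(np.random.SeedSequence(21))
    athletes = draw_athletes(design, root, sd_log_gain=0.0)
    sim = simulate_study(design=design, rng_seed=21, noise=NoiseParams.none(),
                         athletes=athletes)
    feats = features_table(sim.traces)
    curves = normalized_curve_table(concentric_segments(sim.traces))
    report = run_all_models(feats, curves)
    assert (report.fit_table.r2 > 0.99).all()
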