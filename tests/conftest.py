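"""Shared fixtures: deterministic athletes, noise-free jumps, and cached
study-scale replicates for the Monte-Carlo structure checks."""
from __future__ import annotations

import numpy as np
import pytest

from cmjfatigue import (
    AthleteParams, NoiseParams, StudyDesign, features_table, simulate_study,
    simulate_trace,
)
from cmjfatigue.fpca import normalized_curve_table
from cmjfatigue.processing import concentric_segments


@pytest.fixture(scope="session")
def athlete() -> AthleteParams:
    return AthleteParams(
        athlete_id="A01", body_mass_kg=71.0, baseline_rel_peak_force=2.3,
        random_intercept=0.0, double_peak_prob=0.0,
    )


@pytest.fixture(scope="session")
def noisefree_trace(athlete):
    return simulate_trace(athlete, 0.0, rng_seed=1, noise=NoiseParams.none())


@pytest.fixture(scope="session")
def default_study():
    """One default-condition cohort (10 x 3 x 8 x 5 at 600 Hz), with noise."""
    return simulate_study(rng_seed=2024)


@pytest.fixture(scope="session")
def study_features(default_study):
    return features_table(default_study.traces)


@pytest.fixture(scope="session")
def study_curves(default_study):
    return normalized_curve_table(concentric_segments(default_study.traces))


N_REPLICATES = 50


@pytest.fixture(scope="session")
def replicate_tables():
    """Feature + curve tables for 50 seeded study replicates (cached once);
    consumed by the Monte-Carlo structure-recovery checks."""
    out = []
    for seed in range(N_REPLICATES):
        sim = simulate_study(rng_seed=seed)
        out.append(
            (features_table(sim.traces),
             normalized_curve_table(concentric_segments(sim.traces)))
        )
    return out
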