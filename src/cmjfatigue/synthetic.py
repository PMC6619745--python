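"""Seeded synthetic countermovement-jump cohorts.

Emulates the study design the analysis assumes: 10 athletes x 3 repeated-
sprint workloads (low/moderate/high) x 8 measurement time points
(pre-training, immediately post = 0, 0.5, 1, 3, 6, 24, 48 h) x 5 jumps,
sampled at 600 Hz.

Fatigue model
-------------
The relative decrement in peak concentric force is a two-compartment curve

    D(t) = d_w * [ alpha * exp(-t / tau_m)
                   + (1 - alpha) * (t / tau_p) * exp(1 - t / tau_p) ]

with a workload-scaled magnitude ``d_w``.  The first term is short-lived
metabolic fatigue (exponential decay, essentially gone by ~3 h with
tau_m = 1 h); the second is neuromuscular fatigue, an alpha-function peaking
at t = tau_p (default 24 h) and still substantial at 48 h.  D(PRE) = 0.

Trace model
-----------
Each jump's force trace is built directly as
``BW * (1 - dip(t) + propulsion(t))`` from Gaussian pulses — quiet standing,
an unweighting dip, a propulsive pulse scaled so peak force equals
``baseline_relPeakF * (1 - D) * BW`` — followed by a terminal decay to zero
(takeoff), a ballistic flight phase whose duration matches the integrated
takeoff velocity, and a landing spike.  Fatigue also dilates the movement
time by a factor (1 + kappa * D).  A per-jump Bernoulli draw can replace the
single propulsive pulse with a two-Gaussian mixture (the "double peak"
technique artefact).  All randomness flows from one seed via deterministic
per-trial substreams.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .processing import G, ForceTrace, compute_kinematics, takeoff_threshold

logger = logging.getLogger(__name__)

#: sentinel label for the pre-training measurement (never used as a number)
PRE = "PRE"
TIME_LABELS = (PRE, "0", "0.5", "1", "3", "6", "24", "48")
WORKLOADS = ("low", "moderate", "high")


class ConfigurationError(ValueError):
    """Invalid study/fatigue configuration (e.g. unknown workload label)."""


class SimulationError(RuntimeError):
    """Simulation produced a physically impossible jump."""


def time_label_hours(label: str) -> float:
    """Hours post-training for a non-PRE time label."""
    if label == PRE:
        raise ConfigurationError("PRE is a sentinel, not a numeric time")
    return float(label)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FatigueParams:
    """Two-compartment fatigue time-course parameters.

    d_w : relative peak-force decrement scale per workload (unitless)
    alpha : metabolic fraction of the decrement, in [0, 1]
    tau_m : metabolic decay constant, hours
    tau_p : neuromuscular peak time, hours
    """

    d_w: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.05, "moderate": 0.10, "high": 0.15}
    )
    alpha: float = 0.6
    tau_m: float = 1.0
    tau_p: float = 24.0

    def __post_init__(self) -> None:
        vals = list(self.d_w.values())
        if any(v < 0 for v in vals):
            raise ConfigurationError("workload decrements must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError("alpha must lie in [0, 1]")
        if self.tau_m <= 0 or self.tau_p <= 0:
            raise ConfigurationError("tau_m and tau_p must be positive")


@dataclass(frozen=True)
class AthleteParams:
    """One athlete's generating parameters.

    ``baseline_rel_peak_force`` is the population mean (BW multiples) and
    ``random_intercept`` the athlete-level deviation from it; their sum is
    the athlete's true unfatigued relPeakF.  ``tempo`` scales the athlete's
    movement timescale; ``double_peak_prob`` is the per-jump probability of
    the two-peak propulsion artefact.
    """

    athlete_id: str
    body_mass_kg: float
    baseline_rel_peak_force: float
    random_intercept: float
    double_peak_prob: float
    tempo: float = 1.0
    metabolic_gain: float = 1.0      # individual susceptibility multipliers:
    neuromuscular_gain: float = 1.0  # athletes differ in how hard they fatigue

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ConfigurationError("body_mass must be positive")
        if self.rel_peak_force <= 1.0:
            raise ConfigurationError("unfatigued relPeakF must exceed 1 BW")
        if not 0.0 <= self.double_peak_prob <= 1.0:
            raise ConfigurationError("double_peak_prob must lie in [0, 1]")

    @property
    def rel_peak_force(self) -> float:
        return self.baseline_rel_peak_force + self.random_intercept


@dataclass(frozen=True)
class StudyDesign:
    n_athletes: int = 10
    workloads: Sequence[str] = WORKLOADS
    time_labels: Sequence[str] = TIME_LABELS
    jumps_per_set: int = 5
    sample_rate: float = 600.0

    def __post_init__(self) -> None:
        if self.n_athletes < 1 or self.jumps_per_set < 1 or self.sample_rate <= 0:
            raise ConfigurationError("counts and sample rate must be positive")
        hours = [time_label_hours(t) for t in self.time_labels if t != PRE]
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ConfigurationError("post-training time points must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return (
            self.n_athletes * len(self.workloads)
            * len(self.time_labels) * self.jumps_per_set
        )


@dataclass(frozen=True)
class TraceParams:
    """Anatomy of the simulated force trace (times in the undilated clock, s)."""

    quiet_s: float = 0.6
    dip_depth: float = 0.35        # fraction of BW
    dip_center_s: float = 0.25
    dip_width_s: float = 0.06
    prop_center_s: float = 0.55
    prop_width_s: float = 0.09
    double_width_s: float = 0.05   # width of each pulse in the two-peak mixture
    double_ratio: float = 0.8      # second/first peak amplitude ratio
    double_sep_s: float = 0.13
    double_dip_scale: float = 0.5  # shallower countermovement in two-peak jumps
    decay_width_s: float = 0.04    # terminal cosine ramp to zero
    kappa: float = 0.5             # concentric-time dilation per unit decrement
    kappa_shape: float = 5.0       # RFD slowdown per unit neuromuscular decrement
    #   fatigue dilates the whole movement by (1 + kappa*D); the slow
    #   neuromuscular component additionally widens the *rising* flank of the
    #   propulsive pulse by (1 + kappa_shape*D_nm) — impaired rate of force
    #   development, whose relative impairment typically runs several-fold
    #   the peak-force decrement — so the normalised curve shape carries a
    #   neuromuscular signature distinct from the metabolic amplitude drop
    landing_rel_force: float = 2.5
    landing_width_s: float = 0.04
    landing_hold_s: float = 0.25


@dataclass(frozen=True)
class NoiseParams:
    """Jump-to-jump variability: white force noise (N), multiplicative
    amplitude noise on relPeakF, and log-normal timing jitter."""

    force_sd_n: float = 5.0
    amp_sd: float = 0.02
    timing_sd: float = 0.02
    center_jitter_s: float = 0.01  # per-jump jitter of the propulsive peak time
    rfd_sd: float = 0.03           # per-jump variability of the rising-flank width

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# fatigue time course
# ---------------------------------------------------------------------------

def fatigue_components(
    t: float | str, workload: str, params: FatigueParams
) -> tuple[float, float]:
    """(metabolic, neuromuscular) decrement components at ``t`` hours.

    ``t`` may be the PRE sentinel (both components 0).  Unknown workload
    labels raise :class:`ConfigurationError`.  The two compartments drive
    different aspects of the simulated jump: their sum scales the force
    decrement, while only the slow neuromuscular component delays the force
    peak within the concentric phase (a coordination signature that outlasts
    the metabolic dip).
    """
    if isinstance(t, str) and t == PRE:
        return 0.0, 0.0
    t_h = float(t)
    if t_h < 0:
        raise ConfigurationError("post-training time must be >= 0 (or PRE)")
    if workload not in params.d_w:
        raise ConfigurationError(
            f"unknown workload {workload!r}; known: {sorted(params.d_w)}"
        )
    d = params.d_w[workload]
    metabolic = d * params.alpha * np.exp(-t_h / params.tau_m)
    u = t_h / params.tau_p
    neuromuscular = d * (1.0 - params.alpha) * u * np.exp(1.0 - u)
    return float(metabolic), float(neuromuscular)


def fatigue_decrement(t: float | str, workload: str, params: FatigueParams) -> float:
    """Total relative peak-force decrement D in [0, 1) at ``t`` hours
    post-training (metabolic + neuromuscular components)."""
    m, nm = fatigue_components(t, workload, params)
    return m + nm


# ---------------------------------------------------------------------------
# single-trace simulation
# ---------------------------------------------------------------------------

def _gauss(u: np.ndarray, c: float, s: float) -> np.ndarray:
    return np.exp(-0.5 * ((u - c) / s) ** 2)


def _gauss_asym(u: np.ndarray, c: float, s_left: float, s_right: float) -> np.ndarray:
    """Gaussian pulse with different rising (left) and falling (right) widths."""
    s = np.where(u < c, s_left, s_right)
    return np.exp(-0.5 * ((u - c) / s) ** 2)


def simulate_trace(
    athlete: AthleteParams,
    decrement: float,
    rng_seed: int | np.random.Generator,
    sample_rate: float = 600.0,
    params: TraceParams = TraceParams(),
    noise: NoiseParams = NoiseParams.none(),
    double_peak: bool | None = None,
    shape_decrement: float | None = None,
    meta: dict | None = None,
) -> ForceTrace:
    """Simulate one jump trial's force trace.

    Peak propulsive force is calibrated so that the trace's maximum equals
    ``athlete.rel_peak_force * (1 - decrement) * BW`` (times the multiplicative
    amplitude noise), which makes the simulator → feature-extraction loop
    exact in noise-free mode.  Raises :class:`SimulationError` when the
    parameters yield no positive takeoff velocity.
    """
    if not 0.0 <= decrement < 1.0:
        raise SimulationError(f"decrement {decrement} outside [0, 1)")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    p = params
    bw = athlete.body_mass_kg * G
    if double_peak is None:
        double_peak = bool(rng.random() < athlete.double_peak_prob)
    amp_noise = float(np.exp(rng.normal(0.0, noise.amp_sd))) if noise.amp_sd else 1.0
    timing_noise = (
        float(np.exp(rng.normal(0.0, noise.timing_sd))) if noise.timing_sd else 1.0
    )
    target_rel = athlete.rel_peak_force * (1.0 - decrement) * amp_noise
    if target_rel <= 1.0:
        raise SimulationError(
            f"target relPeakF {target_rel:.3f} <= 1 BW (decrement={decrement})"
        )

    # dilated movement clock: fatigue and athlete tempo stretch the motion
    dilation = athlete.tempo * (1.0 + p.kappa * decrement) * timing_noise
    dt = 1.0 / sample_rate

    d_shape = decrement if shape_decrement is None else shape_decrement
    jitter = float(rng.normal(0.0, noise.center_jitter_s)) if noise.center_jitter_s else 0.0
    rfd_noise = float(np.exp(rng.normal(0.0, noise.rfd_sd))) if noise.rfd_sd else 1.0
    widen = (1.0 + p.kappa_shape * d_shape) * rfd_noise  # slower force rise
    c0 = p.prop_center_s + jitter
    if double_peak:
        centers = (c0, c0 + p.double_sep_s)
        widths = (p.double_width_s, p.double_width_s)
        amps = (1.0, p.double_ratio)
    else:
        centers, widths, amps = (c0,), (p.prop_width_s,), (1.0,)
    decay_start = centers[-1] + 3.0 * widths[-1]
    motion_dur = (decay_start + p.decay_width_s + 0.05) * dilation

    n_quiet = int(round(p.quiet_s * sample_rate))
    n_motion = int(round(motion_dur * sample_rate))
    u = (np.arange(n_motion) * dt) / dilation  # undilated clock

    # two-peak jumps pair the technique artefact with a shallower
    # countermovement, keeping the concentric onset ahead of the first peak
    dip_depth = p.dip_depth * (p.double_dip_scale if double_peak else 1.0)
    dip = dip_depth * _gauss(u, p.dip_center_s, p.dip_width_s)
    # the first pulse's rising flank widens with neuromuscular fatigue
    shape = amps[0] * _gauss_asym(u, centers[0], widths[0] * widen, widths[0])
    for a, c, s in zip(amps[1:], centers[1:], widths[1:]):
        shape = shape + a * _gauss(u, c, s)
    shape /= shape.max()
    ramp = np.clip((u - decay_start) / p.decay_width_s, 0.0, 1.0)
    decay = 0.5 * (1.0 + np.cos(np.pi * ramp))

    # calibrate the pulse amplitude so the realised maximum hits the target
    amp = target_rel - 1.0
    for _ in range(4):
        rel = (1.0 - dip + amp * shape) * decay
        amp += target_rel - rel.max()
    rel_motion = (1.0 - dip + amp * shape) * decay

    force = np.concatenate([np.ones(n_quiet), rel_motion]) * bw
    if noise.force_sd_n:
        force = force + rng.normal(0.0, noise.force_sd_n, size=force.size)

    # takeoff velocity from the generated pre-flight trace itself
    t_pre = np.arange(force.size) * dt
    pre_trace = ForceTrace(t_pre, force, sample_rate)
    kin = compute_kinematics(pre_trace, athlete.body_mass_kg)
    thr = takeoff_threshold(bw)
    peak = int(np.argmax(force))
    below = np.nonzero(force[peak + 1:] < thr)[0]
    if below.size == 0:
        raise SimulationError("no takeoff: force never decays below threshold")
    takeoff = peak + 1 + int(below[0])
    v_to = float(kin.velocity[takeoff])
    if v_to <= 0.05:
        raise SimulationError(
            f"no positive takeoff velocity (v={v_to:.3f} m/s); "
            f"check dip_depth={p.dip_depth} vs propulsion amplitude {amp:.3f}"
        )

    # upward velocity zero-crossing = true concentric onset (ground truth)
    v = kin.velocity[:takeoff]
    crossings = np.nonzero((v[:-1] < 0) & (v[1:] >= 0))[0]
    onset = int(crossings[-1]) + 1 if crossings.size else None

    # flight (force ~ 0) for the ballistic duration, then a landing pulse
    flight_s = 2.0 * v_to / G
    n_flight = max(int(round(flight_s * sample_rate)), 1)
    n_land = int(round((4.0 * p.landing_width_s + p.landing_hold_s) * sample_rate))
    u_land = np.arange(n_land) * dt
    land = bw * (
        1.0 + (p.landing_rel_force - 1.0)
        * _gauss(u_land, 2.0 * p.landing_width_s, p.landing_width_s)
    )
    tail = np.concatenate([np.zeros(n_flight), land])
    if noise.force_sd_n:
        tail = tail + rng.normal(0.0, noise.force_sd_n, size=tail.size)

    force = np.concatenate([force[:takeoff], tail])
    time = np.arange(force.size) * dt
    info = dict(meta or {})
    info.update(
        athlete_id=athlete.athlete_id,
        body_mass_kg=athlete.body_mass_kg,
        bodyweight_n=bw,
        decrement=decrement,
        rel_peak_force_true=target_rel,
        double_peak=double_peak,
        dilation=dilation,
        v_takeoff=v_to,
        onset_index_true=onset,
        takeoff_index_true=takeoff,
        t_con_true=(takeoff - onset) * dt if onset is not None else np.nan,
        flight_s_true=flight_s,
    )
    return ForceTrace(time, force, sample_rate, meta=info)


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class StudySimulation:
    """Traces plus the generating truth for a simulated study."""

    design: StudyDesign
    fatigue: FatigueParams
    athletes: list[AthleteParams]
    traces: list[ForceTrace]
    truth: pd.DataFrame  # one row per trial: labels + generating parameters


def draw_athletes(
    design: StudyDesign,
    rng: np.random.Generator,
    mean_mass_kg: float = 71.0,
    sd_mass_kg: float = 12.4,
    mean_rel_peak_force: float = 2.3,
    sd_random_intercept: float = 0.3,
    sd_tempo: float = 0.1,
    double_peak_prob_range: tuple[float, float] = (0.05, 0.3),
    sd_log_gain: float = 0.35,
    gain_correlation: float = 0.6,
) -> list[AthleteParams]:
    """Draw a cohort: cohort size/mass match the study population (71 +/- 12.4 kg);
    athlete-level random intercepts dominate workload effects, as in the data.

    Fatigue susceptibility varies between athletes as correlated log-normal
    gains on the metabolic and neuromuscular components: athletes who dip
    hard immediately after training also tend to carry more prolonged
    fatigue, without the two being redundant.
    """
    out = []
    for i in range(design.n_athletes):
        z1, z2 = rng.standard_normal(2)
        z2 = gain_correlation * z1 + np.sqrt(1 - gain_correlation**2) * z2
        out.append(
            AthleteParams(
                athlete_id=f"A{i + 1:02d}",
                body_mass_kg=float(np.clip(rng.normal(mean_mass_kg, sd_mass_kg), 45.0, 110.0)),
                baseline_rel_peak_force=mean_rel_peak_force,
                random_intercept=float(np.clip(rng.normal(0.0, sd_random_intercept), -0.8, 0.8)),
                double_peak_prob=float(rng.uniform(*double_peak_prob_range)),
                tempo=float(np.clip(rng.normal(1.0, sd_tempo), 0.7, 1.3)),
                metabolic_gain=float(np.exp(sd_log_gain * z1)),
                neuromuscular_gain=float(np.exp(sd_log_gain * z2)),
            )
        )
    return out


def simulate_study(
    design: StudyDesign = StudyDesign(),
    fatigue: FatigueParams = FatigueParams(),
    rng_seed: int = 0,
    trace_params: TraceParams = TraceParams(),
    noise: NoiseParams = NoiseParams(),
    athletes: list[AthleteParams] | None = None,
) -> StudySimulation:
    """Simulate the full study design; returns traces and the truth table.

    Exactly ``n_athletes * |workloads| * |time_points| * jumps_per_set``
    traces are produced.  Per-trial randomness uses substreams spawned
    deterministically from ``rng_seed``.
    """
    root = np.random.SeedSequence(rng_seed)
    athlete_ss, trial_root = root.spawn(2)
    if athletes is None:
        athletes = draw_athletes(design, np.random.default_rng(athlete_ss))
    if len(athletes) != design.n_athletes:
        raise ConfigurationError("athletes list does not match design.n_athletes")

    trial_streams = trial_root.spawn(design.n_trials)
    traces: list[ForceTrace] = []
    rows = []
    k = 0
    for athlete in athletes:
        for workload in design.workloads:
            for tp in design.time_labels:
                t_arg = tp if tp == PRE else float(tp)
                d_met, d_nm = fatigue_components(t_arg, workload, fatigue)
                d_met *= athlete.metabolic_gain
                d_nm *= athlete.neuromuscular_gain
                d = min(d_met + d_nm, 0.6)  # individual response, kept physical
                for jump in range(1, design.jumps_per_set + 1):
                    rng = np.random.default_rng(trial_streams[k])
                    k += 1
                    trace = simulate_trace(
                        athlete, d, rng,
                        sample_rate=design.sample_rate,
                        params=trace_params, noise=noise,
                        shape_decrement=d_nm,
                        meta=dict(workload=workload, time_point=tp, jump=jump),
                    )
                    traces.append(trace)
                    rows.append(
                        {
                            "athlete_id": athlete.athlete_id,
                            "workload": workload,
                            "time_point": tp,
                            "jump": jump,
                            "decrement_metabolic": d_met,
                            "decrement_neuromuscular": d_nm,
                            **{
                                key: trace.meta[key]
                                for key in (
                                    "body_mass_kg", "bodyweight_n", "decrement",
                                    "rel_peak_force_true", "double_peak", "dilation",
                                    "v_takeoff", "t_con_true",
                                )
                            },
                        }
                    )
    logger.info("simulated %d traces (%d athletes)", len(traces), design.n_athletes)
    return StudySimulation(design, fatigue, list(athletes), traces, pd.DataFrame(rows))
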