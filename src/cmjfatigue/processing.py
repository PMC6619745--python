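"""Concentric-phase extraction from countermovement-jump force traces.

A countermovement jump (CMJ) recorded on a force plate yields a vertical
ground-reaction-force trace: quiet standing at bodyweight, an unweighting
dip, a propulsive push whose peak exceeds bodyweight, and a drop to ~0 N at
takeoff.  The concentric phase is the portion before takeoff during which
the change in displacement is positive (upward movement).  This module
locates that phase and derives the four scalar performance features used
throughout the package:

* ``rel_peak_force``  — peak concentric force, in bodyweight multiples
* ``rel_peak_power``  — peak concentric power per kg of body mass (W/kg)
* ``t_con_s``         — concentric duration (s)
* ``t_peak_force_s``  — time from concentric onset to peak force (s)

Velocity and displacement come from impulse–momentum integration
(a = F/m − g, cumulative trapezoid); no filtering is applied by default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

G = 9.81  # m/s^2, standard gravity

#: canonical feature column order used across the package
FEATURE_COLUMNS = ("rel_peak_force", "rel_peak_power", "t_con_s", "t_peak_force_s")


class PhaseDetectionError(RuntimeError):
    """A phase of the jump (quiet standing, flight, concentric) could not be found."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ForceTrace:
    """One jump trial: uniformly sampled vertical ground-reaction force.

    Parameters
    ----------
    time : array of sample times, s (uniform within 1e-9 s)
    force : vertical force, N
    sample_rate : Hz
    meta : trial labels (athlete_id, workload, time_point, jump, ...)
    """

    time: np.ndarray
    force: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.force.shape or self.time.ndim != 1:
            raise ValueError("time and force must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("force contains non-finite values")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.any(np.abs(dt - dt[0]) > 1e-9):
                raise ValueError("sampling is not uniform within 1e-9 s")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass
class BodyweightEstimate:
    bodyweight_n: float
    body_mass_kg: float
    sd_n: float           # quiet-window standard deviation, for quality control


@dataclass
class Kinematics:
    """Velocity/displacement/power series derived from a trace by integration."""

    velocity: np.ndarray      # m/s
    displacement: np.ndarray  # m
    power: np.ndarray         # W (= force * velocity)


@dataclass
class ConcentricSegment:
    """The concentric portion of one jump, re-zeroed at concentric onset.

    ``duration`` (= t_con) and the onset time use sub-sample linear
    interpolation of the velocity zero-crossing and the takeoff threshold
    crossing, so extracted times are not quantised to the sample grid.
    """

    time: np.ndarray       # s, re-zeroed at (interpolated) onset
    force: np.ndarray      # N
    velocity: np.ndarray   # m/s
    power: np.ndarray      # W
    bodyweight_n: float
    body_mass_kg: float
    duration: float        # s, interpolated onset -> takeoff
    onset_index: int
    takeoff_index: int
    fallback: bool = False  # True when the 0.9*BW force-rise fallback was used
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.time) < 10:
            raise PhaseDetectionError("degenerate concentric phase (<10 samples)")


@dataclass(frozen=True)
class CMJFeatures:
    rel_peak_force: float   # bodyweight multiples
    rel_peak_power: float   # W/kg
    t_con_s: float          # s
    t_peak_force_s: float   # s

    def __post_init__(self) -> None:
        if not (self.t_peak_force_s <= self.t_con_s + 1e-12):
            raise ValueError("t_peak_force exceeds concentric duration")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def estimate_bodyweight(
    trace: ForceTrace, window_s: float = 0.5, max_sd_n: float = 10.0
) -> BodyweightEstimate:
    """Estimate bodyweight (N) and body mass (kg) from the quiet-standing window.

    The trace must begin with at least ``window_s`` seconds of quiet standing;
    the mean force over that window is the bodyweight and mass = BW / g.
    Raises :class:`PhaseDetectionError` if the window's standard deviation
    exceeds ``max_sd_n`` (no stable quiet standing).
    """
    n = int(round(window_s * trace.sample_rate))
    if n < 2 or n > len(trace):
        raise ValueError(f"quiet window of {window_s} s does not fit the trace")
    w = trace.force[:n]
    sd = float(np.std(w))
    if sd > max_sd_n:
        raise PhaseDetectionError(
            f"no stable quiet standing: window sd {sd:.1f} N > {max_sd_n:.1f} N"
        )
    bw = float(np.mean(w))
    return BodyweightEstimate(bw, bw / G, sd)


def compute_kinematics(trace: ForceTrace, body_mass_kg: float) -> Kinematics:
    """Velocity, displacement and power by impulse–momentum integration.

    a(t) = F(t)/m − g; velocity and displacement by cumulative trapezoid from
    rest (the first sample is assumed to be quiet standing with v = 0);
    power(t) = F(t)·v(t).
    """
    if body_mass_kg <= 0:
        raise ValueError("body_mass must be positive")
    accel = trace.force / body_mass_kg - G
    velocity = cumulative_trapezoid(accel, trace.time, initial=0.0)
    displacement = cumulative_trapezoid(velocity, trace.time, initial=0.0)
    return Kinematics(velocity, displacement, trace.force * velocity)


def takeoff_threshold(bodyweight_n: float) -> float:
    """Default takeoff threshold: max(10 N, 2% of bodyweight)."""
    return max(10.0, 0.02 * bodyweight_n)


def detect_takeoff(trace: ForceTrace, threshold: float) -> int:
    """First sample index after the global propulsion peak where force < threshold.

    Raises :class:`PhaseDetectionError` when no sub-threshold sample follows the
    peak (no flight phase) and :class:`ValueError` for a threshold at or above
    the peak force (degenerate).
    """
    if threshold >= float(np.max(trace.force)):
        raise ValueError(
            f"takeoff threshold {threshold:.1f} N is not below peak force "
            f"{np.max(trace.force):.1f} N"
        )
    below = np.nonzero(trace.force < threshold)[0]
    if below.size == 0:
        raise PhaseDetectionError("no flight phase detected (force never drops below threshold)")
    first_below = int(below[0])
    # the propulsion peak is the maximum before flight; a landing spike later
    # in the trace may exceed it and must not be mistaken for propulsion
    if first_below == 0 or threshold >= float(np.max(trace.force[:first_below])):
        raise ValueError("takeoff threshold is not below the propulsion peak")
    return first_below


def detect_landing(trace: ForceTrace, takeoff_index: int, threshold: float) -> int:
    """First index at/after takeoff where force rises back above threshold."""
    above = np.nonzero(trace.force[takeoff_index:] >= threshold)[0]
    if above.size == 0:
        raise PhaseDetectionError("no landing detected after takeoff")
    return takeoff_index + int(above[0])


def _interp_crossing(t0: float, t1: float, v0: float, v1: float) -> float:
    """Linear-interpolated abscissa of the zero crossing between two samples."""
    if v1 == v0:
        return t0
    return t0 + (t1 - t0) * (-v0) / (v1 - v0)


def extract_concentric(
    trace: ForceTrace,
    window_s: float = 0.5,
    max_sd_n: float = 10.0,
    threshold_n: float | None = None,
) -> ConcentricSegment:
    """Extract the concentric phase: [velocity zero-crossing onset, takeoff).

    Onset is the last upward zero-crossing of velocity before takeoff, i.e.
    the start of the interval in which the change in displacement is positive.
    If velocity is never strictly negative before takeoff (no countermovement),
    a fallback anchor is used — the first sample after the unweighting minimum
    where force rises through 0.9·BW — and the segment is flagged.
    """
    bw = estimate_bodyweight(trace, window_s=window_s, max_sd_n=max_sd_n)
    kin = compute_kinematics(trace, bw.body_mass_kg)
    thr = takeoff_threshold(bw.bodyweight_n) if threshold_n is None else threshold_n
    takeoff = detect_takeoff(trace, thr)

    v = kin.velocity
    # onset = last upward zero crossing preceded by a genuine countermovement
    # (v below -2 cm/s, so numerical drift in quiet standing never counts)
    v_eps = 0.02
    neg = np.nonzero(v[:takeoff] < -v_eps)[0]
    onset = None
    if neg.size:
        after = np.nonzero(v[neg[-1]:takeoff] >= 0.0)[0]
        if after.size:
            onset = int(neg[-1]) + int(after[0])  # first sample with v >= 0
    fallback = onset is None
    if not fallback:
        t_onset = _interp_crossing(
            trace.time[onset - 1], trace.time[onset], v[onset - 1], v[onset]
        )
    else:
        peak = int(np.argmax(trace.force[:takeoff]))
        trough = int(np.argmin(trace.force[:peak])) if peak > 0 else 0
        rise = np.nonzero(trace.force[trough:takeoff] >= 0.9 * bw.bodyweight_n)[0]
        if rise.size == 0:
            raise PhaseDetectionError("fallback onset: force never rises through 0.9*BW")
        onset = trough + int(rise[0])
        t_onset = trace.time[onset]
        logger.info("concentric onset fallback (0.9*BW anchor) used for %s", trace.meta)

    # takeoff time, interpolated at the threshold crossing
    t_takeoff = _interp_crossing(
        trace.time[takeoff - 1], trace.time[takeoff],
        trace.force[takeoff - 1] - thr, trace.force[takeoff] - thr,
    )

    seg = slice(onset, takeoff)
    return ConcentricSegment(
        time=trace.time[seg] - t_onset,
        force=trace.force[seg],
        velocity=v[seg],
        power=kin.power[seg],
        bodyweight_n=bw.bodyweight_n,
        body_mass_kg=bw.body_mass_kg,
        duration=t_takeoff - t_onset,
        onset_index=onset,
        takeoff_index=takeoff,
        fallback=fallback,
        meta=dict(trace.meta),
    )


def _refined_peak_time(time: np.ndarray, values: np.ndarray) -> float:
    """Time of the maximum, refined by a parabola through the three samples
    around the discrete argmax (earliest sample on ties); boundary maxima are
    returned unrefined."""
    i = int(np.argmax(values))
    if i == 0 or i == len(values) - 1:
        return float(time[i])
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a strict local max in the quadratic sense
        return float(time[i])
    delta = 0.5 * (y0 - y2) / denom
    dt = time[i + 1] - time[i]
    return float(time[i] + np.clip(delta, -0.5, 0.5) * dt)


def extract_features(segment: ConcentricSegment) -> CMJFeatures:
    """The four scalar features of a concentric segment.

    Peak force/power values are the discrete maxima (ties broken by earliest
    sample); the *time* of peak force is parabola-refined to sub-sample
    resolution.  A peak at the final sample maps t_peak_force to t_con.
    """
    rel_peak_force = float(np.max(segment.force)) / segment.bodyweight_n
    rel_peak_power = float(np.max(segment.power)) / segment.body_mass_kg
    i = int(np.argmax(segment.force))
    if i == len(segment.force) - 1:
        t_peak = segment.duration
    else:
        t_peak = min(_refined_peak_time(segment.time, segment.force), segment.duration)
    return CMJFeatures(rel_peak_force, rel_peak_power, segment.duration, max(t_peak, 0.0))


def count_propulsion_peaks(segment: ConcentricSegment, prominence_frac: float = 0.05) -> int:
    """Number of propulsion peaks: local force maxima above bodyweight with
    prominence >= prominence_frac * BW (captures the double-peak artefact)."""
    bw = segment.bodyweight_n
    peaks, _ = find_peaks(segment.force, height=bw, prominence=prominence_frac * bw)
    # an interior discrete maximum at the first/last sample is not reported by
    # find_peaks; the propulsion peak of a CMJ is interior by construction
    return int(len(peaks))


# ---------------------------------------------------------------------------
# batch helpers
# ---------------------------------------------------------------------------

META_COLUMNS = ("athlete_id", "workload", "time_point", "jump")


def features_table(
    traces: Iterable[ForceTrace],
    window_s: float = 0.5,
    max_sd_n: float = 10.0,
    on_error: str = "raise",
) -> pd.DataFrame:
    """Long-format feature table for a collection of traces.

    Columns: athlete_id, workload, time_point, jump, the four features,
    n_peaks and fallback_flag.  ``on_error='skip'`` drops failing trials with
    a logged count instead of raising.
    """
    rows, failures = [], 0
    for trace in traces:
        try:
            seg = extract_concentric(trace, window_s=window_s, max_sd_n=max_sd_n)
            f = extract_features(seg)
        except (PhaseDetectionError, ValueError):
            if on_error != "skip":
                raise
            failures += 1
            continue
        row = {k: trace.meta.get(k) for k in META_COLUMNS}
        row.update(
            rel_peak_force=f.rel_peak_force,
            rel_peak_power=f.rel_peak_power,
            t_con_s=f.t_con_s,
            t_peak_force_s=f.t_peak_force_s,
            n_peaks=count_propulsion_peaks(seg),
            fallback_flag=seg.fallback,
        )
        rows.append(row)
    if failures:
        logger.warning("feature extraction skipped %d failing trials", failures)
    return pd.DataFrame(rows)


def concentric_segments(
    traces: Iterable[ForceTrace],
    window_s: float = 0.5,
    max_sd_n: float = 10.0,
    on_error: str = "raise",
) -> list[ConcentricSegment]:
    """Concentric segments (with trial meta attached) for a trace collection."""
    out, failures = [], 0
    for trace in traces:
        try:
            out.append(extract_concentric(trace, window_s=window_s, max_sd_n=max_sd_n))
        except (PhaseDetectionError, ValueError):
            if on_error != "skip":
                raise
            failures += 1
    if failures:
        logger.warning("segment extraction skipped %d failing trials", failures)
    return out
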