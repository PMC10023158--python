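"""Eye-movement kinematics: pupil-to-angle conversion, saccade handling,
and optokinetic-reflex gain.

The pipeline is: tracked pupil landmarks → angular eye position (arcsin
geometry), saccade (fast-nystagmus) detection from velocity/acceleration
thresholds, saccade removal by velocity substitution and reintegration, and
per-half-cycle slow-phase gain (eye velocity / stimulus velocity) plus
fast/slow nystagmus summary statistics. Superior eye movement is positive θ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import StimulusProfile

__all__ = [
    "PupilSample",
    "EyeTrace",
    "Rp0Model",
    "SaccadeInterval",
    "pupil_to_angle",
    "angle_to_pupil",
    "fit_rp0",
    "detect_saccades",
    "remove_saccades",
    "slow_phase_gain",
    "nystagmus_stats",
]


@dataclass
class PupilSample:
    """One tracked frame: pupil offsets from the eye center, camera units."""

    dx: float     # horizontal pupil-to-eye-center distance
    dy: float     # vertical distance
    rp0: float    # radius of rotation between pupil and eye center
    t: float = 0.0


@dataclass
class SaccadeInterval:
    start: float      # s
    end: float        # s
    direction: str    # superior | inferior


@dataclass
class EyeTrace:
    """Vertical (and optionally horizontal) eye angle on a uniform grid."""

    t: np.ndarray
    theta: np.ndarray               # degrees, positive = superior
    phi: np.ndarray | None = None   # degrees, optional horizontal
    saccades: list | None = None    # list[SaccadeInterval]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        steps = np.diff(self.t)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def velocity(self) -> np.ndarray:
        """Backward-difference Δθ/Δt, °/s; first sample 0."""
        v = np.zeros_like(self.theta)
        v[1:] = np.diff(self.theta) / self.dt
        return v


def pupil_to_angle(sample: PupilSample) -> tuple[float, float]:
    """Convert a pupil offset to (phi, theta) angular eye position, degrees.

    θ = arcsin(Δy / Rp0) and ϕ = arcsin(Δx / sqrt(Rp0² − Δy²)): the pupil
    moves on a sphere of radius Rp0 about the eye's center of rotation.
    """
    if sample.rp0 <= 0:
        raise ValueError("rp0 must be positive")
    if abs(sample.dy) >= sample.rp0:
        raise ValueError("|dy| must be smaller than rp0")
    denom = np.sqrt(sample.rp0 ** 2 - sample.dy ** 2)
    if abs(sample.dx) >= denom:
        raise ValueError("|dx| out of the physical gimbal range")
    theta = np.rad2deg(np.arcsin(sample.dy / sample.rp0))
    phi = np.rad2deg(np.arcsin(sample.dx / denom))
    return float(phi), float(theta)


def angle_to_pupil(phi_deg: float, theta_deg: float, rp0: float) -> PupilSample:
    """Forward projection of an eye angle to pupil offsets (inverse of
    :func:`pupil_to_angle`)."""
    dy = rp0 * np.sin(np.deg2rad(theta_deg))
    dx = np.sin(np.deg2rad(phi_deg)) * np.sqrt(rp0 ** 2 - dy ** 2)
    return PupilSample(dx=float(dx), dy=float(dy), rp0=rp0)


@dataclass
class Rp0Model:
    """Linear map from pupil diameter to the radius of rotation Rp0."""

    slope: float
    intercept: float

    def predict(self, pupil_diameter: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(pupil_diameter,
                                                        dtype=float)


def fit_rp0(pupil_diameters: np.ndarray, rp0_values: np.ndarray) -> Rp0Model:
    """Ordinary least-squares line through (pupil diameter, Rp0) points,
    as measured by swinging the camera at several luminances."""
    d = np.asarray(pupil_diameters, dtype=float)
    r = np.asarray(rp0_values, dtype=float)
    if np.unique(d).size < 2:
        raise ValueError("need at least two distinct pupil sizes")
    slope, intercept = np.polyfit(d, r, 1)
    return Rp0Model(slope=float(slope), intercept=float(intercept))


def detect_saccades(trace: EyeTrace,
                    velocity_thresh: float = 50.0,
                    accel_thresh: float = 2000.0,
                    min_gap_s: float = 0.05) -> list[SaccadeInterval]:
    """Find fast-nystagmus intervals by velocity/acceleration thresholds.

    Samples whose |velocity| exceeds ``velocity_thresh`` (°/s) or whose
    |acceleration| exceeds ``accel_thresh`` (°/s²) are merged into
    intervals; intervals closer than ``min_gap_s`` are fused. Each interval
    is labeled superior/inferior by its displacement sign.
    """
    v = trace.velocity()
    a = np.zeros_like(v)
    a[1:] = np.diff(v) / trace.dt
    hot = (np.abs(v) > velocity_thresh) | (np.abs(a) > accel_thresh)
    idx = np.flatnonzero(hot)
    if idx.size == 0:
        return []
    gap = max(int(round(min_gap_s / trace.dt)), 1)
    breaks = np.flatnonzero(np.diff(idx) > gap)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    out = []
    for s, e in zip(starts, ends):
        # the flagged velocity at sample k describes the step (k-1, k]
        i0 = max(s - 1, 0)
        disp = trace.theta[e] - trace.theta[i0]
        out.append(SaccadeInterval(
            start=float(trace.t[i0]), end=float(trace.t[e]),
            direction="superior" if disp >= 0 else "inferior"))
    return out


def remove_saccades(trace: EyeTrace,
                    intervals: list[SaccadeInterval]) -> EyeTrace:
    """Replace saccadic velocity with the pre-onset velocity, reintegrate.

    Within each interval Δθ/Δt is set to its value immediately prior to the
    saccade onset (0 °/s when the saccade starts at the first sample), and
    the position is rebuilt by cumulative integration from the original
    starting position.
    """
    v = trace.velocity()
    for iv in intervals:
        i0 = int(np.searchsorted(trace.t, iv.start, side="left"))
        i1 = int(np.searchsorted(trace.t, iv.end, side="right"))
        pre = v[i0] if i0 >= 1 else 0.0
        v[max(i0 + 1, 1):i1] = pre
    theta = trace.theta[0] + np.concatenate(([0.0], np.cumsum(v[1:]))) * trace.dt
    return EyeTrace(t=trace.t.copy(), theta=theta, phi=trace.phi,
                    saccades=list(intervals))


def _stage_bounds(stimulus: StimulusProfile) -> list[tuple[float, float, str]]:
    """Half-oscillation stages (start, end, label) from the stimulus
    velocity sign within the moving window."""
    lo, hi = stimulus.moving_window
    sel = (stimulus.t >= lo) & (stimulus.t <= hi)
    t = stimulus.t[sel]
    v = stimulus.velocity[sel]
    sign = np.sign(v)
    sign[sign == 0] = 1
    flips = np.flatnonzero(np.diff(sign) != 0)
    bounds = np.concatenate(([t[0]], t[flips + 1], [t[-1]]))
    stages = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (b0 + b1)
        label = "superior" if np.interp(mid, t, v) > 0 else "inferior"
        stages.append((float(b0), float(b1), label))
    return stages


def slow_phase_gain(trace: EyeTrace, stimulus: StimulusProfile) -> pd.DataFrame:
    """Slow-phase OKR gain per half-oscillation stage.

    For each half cycle of the oscillating stimulus, gain is the mean eye
    velocity divided by the mean stimulus velocity over that stage; the
    trace should already be desaccaded. Returns a table with columns
    ``cycle``, ``stage`` (superior/inferior), and ``gain``.
    """
    if stimulus.kind != "oscillating":
        raise ValueError("slow-phase gain is defined for oscillating stimuli")
    v_eye = trace.velocity()
    rows = []
    counters = {"superior": 0, "inferior": 0}
    for (b0, b1, label) in _stage_bounds(stimulus):
        sel_e = (trace.t > b0) & (trace.t <= b1)
        sel_s = (stimulus.t > b0) & (stimulus.t <= b1)
        if not sel_e.any() or not sel_s.any():
            continue
        mean_stim = stimulus.velocity[sel_s].mean()
        if mean_stim == 0:
            continue
        rows.append({"cycle": counters[label], "stage": label,
                     "gain": float(v_eye[sel_e].mean() / mean_stim)})
        counters[label] += 1
    return pd.DataFrame(rows)


def nystagmus_stats(trace: EyeTrace, intervals: list[SaccadeInterval],
                    stimulus: StimulusProfile,
                    subtract_drift: bool = False) -> dict:
    """Fast-nystagmus rates, slow-phase distances, and baseline drift.

    Fast rate (Hz, per direction) counts labeled saccades over the moving
    phase. Cumulative slow distance (°, per direction) integrates the
    desaccaded velocity, split by sign. Drift (°/s) is the median raw
    velocity during the static flanks; when ``subtract_drift`` is set it is
    removed from the slow-phase velocity before integrating (appropriate
    for oscillating epochs, where the eye stays near neutral).
    """
    lo, hi = stimulus.moving_window
    duration = hi - lo
    if duration <= 0:
        raise ValueError("moving epoch has zero duration")
    desacc = remove_saccades(trace, intervals)
    v = desacc.velocity()
    flank = (trace.t < lo) | (trace.t > hi)
    v_raw = trace.velocity()
    drift = float(np.median(v_raw[flank])) if flank.any() else 0.0
    moving = (trace.t >= lo) & (trace.t <= hi)
    v_slow = v[moving] - (drift if subtract_drift else 0.0)
    n_sup = sum(1 for iv in intervals
                if iv.direction == "superior" and lo <= iv.start <= hi)
    n_inf = sum(1 for iv in intervals
                if iv.direction == "inferior" and lo <= iv.start <= hi)
    return {
        "fast_rate_superior_hz": n_sup / duration,
        "fast_rate_inferior_hz": n_inf / duration,
        "slow_distance_superior_deg":
            float(np.sum(np.maximum(v_slow, 0.0)) * trace.dt),
        "slow_distance_inferior_deg":
            float(np.sum(np.maximum(-v_slow, 0.0)) * trace.dt),
        "drift_deg_s": drift,
    }
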