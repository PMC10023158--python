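"""Synthetic inputs for the oDSGC → OKR pipeline.

Everything the analysis consumes can be generated here: grating / drifting-bar
stimulus waveforms, populations of Superior and Inferior oDSGC tuning curves,
per-direction conductance sets for the membrane model, population firing
rates over a grating oscillation cycle, and eye-position traces with labeled
saccades. Generators are pure functions of (params, seed): the same call is
bit-reproducible.

The default parameters encode the empirical effect structure the pipeline is
meant to detect: Superior oDSGCs respond more and are more broadly tuned
than Inferior oDSGCs, both cell types sharpen at low contrast, inhibition is
direction-tuned while excitation is untuned and stronger onto Superior
cells, and slow-phase eye velocity follows stimulus velocity with a gain
below 1, interrupted by resetting saccades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conductance import ConductanceSet
from .tuning import DirectionalResponse, DIRECTIONS_8

__all__ = [
    "StimulusProfile",
    "SyntheticPopulationParams",
    "SyntheticCell",
    "EyeTraceData",
    "make_stimulus",
    "make_population",
    "make_conductance_set",
    "make_grating_rates",
    "make_eye_trace",
]

# retinal-coordinate preferred axes: Superior oDSGCs prefer dorsal-to-ventral
# motion on the retina (toward the ventral pole at 270°), Inferior the reverse
TYPE_PD_DEG = {"Superior": 270.0, "Inferior": 90.0}


@dataclass
class StimulusProfile:
    """Position/velocity waveform of a grating or bar stimulus.

    Position is in degrees (grating phase position, positive = superior in
    visual space); velocity is its discrete time-derivative, so the
    cumulative sum of velocity reproduces position exactly.
    """

    t: np.ndarray          # s, uniform grid
    position: np.ndarray   # degrees
    velocity: np.ndarray   # degrees/s
    kind: str              # unidirectional | oscillating | drifting_bar
    params: dict

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def moving_window(self) -> tuple[float, float]:
        """(start, end) seconds of the moving phase."""
        flank = self.params.get("flank_s", 0.0)
        return flank, flank + self.params["moving_s"]

    def n_complete_cycles(self) -> int:
        """Complete oscillation cycles in the moving phase, counted from
        upward zero crossings of the position waveform."""
        if self.kind != "oscillating":
            raise ValueError("cycle count is defined for oscillating stimuli")
        lo, hi = self.moving_window
        sel = (self.t >= lo - 1e-9) & (self.t <= hi + 1e-9)
        p = self.position[sel]
        tol = 1e-6 * max(np.abs(p).max(), 1.0)
        # upward zero crossings are cycle boundaries; one complete cycle
        # spans two consecutive boundaries
        n_cross = int(np.count_nonzero((p[:-1] <= tol) & (p[1:] > tol)))
        if abs(p[-1]) < tol and p.size > 1 and p[-2] < -tol:
            n_cross += 1  # window ends rising exactly through zero
        return max(n_cross - 1, 0)


def make_stimulus(kind: str, params: dict | None = None,
                  dt: float = 0.01) -> StimulusProfile:
    """Build a stimulus waveform on a uniform grid.

    kinds and defaults
    ------------------
    ``oscillating``: 20 s static flank, 120 s sinusoidal position
        A·sin(2πt/T) with amplitude 20° and period 15 s (zero phase at
        moving-phase onset), 20 s static flank.
    ``unidirectional``: 20 s static, 60 s drift at 10 °/s, 20 s static.
    ``drifting_bar``: bar sweep at 10 °/s for 4 s, no flanks.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = dict(params or {})
    if kind == "oscillating":
        p.setdefault("amplitude_deg", 20.0)
        p.setdefault("period_s", 15.0)
        p.setdefault("moving_s", 120.0)
        p.setdefault("flank_s", 20.0)
        p.setdefault("spatial_freq_cpd", 0.15)
        if p["period_s"] <= 0:
            raise ValueError("period must be positive")
        total = 2 * p["flank_s"] + p["moving_s"]
        t = np.arange(0.0, total + dt / 2, dt)
        pos = np.zeros_like(t)
        moving = (t >= p["flank_s"]) & (t <= p["flank_s"] + p["moving_s"])
        pos[moving] = p["amplitude_deg"] * np.sin(
            2 * np.pi * (t[moving] - p["flank_s"]) / p["period_s"])
    elif kind == "unidirectional":
        p.setdefault("speed_deg_s", 10.0)
        p.setdefault("moving_s", 60.0)
        p.setdefault("flank_s", 20.0)
        p.setdefault("spatial_freq_cpd", 0.15)
        total = 2 * p["flank_s"] + p["moving_s"]
        t = np.arange(0.0, total + dt / 2, dt)
        pos = np.clip(t - p["flank_s"], 0.0, p["moving_s"]) * p["speed_deg_s"]
    elif kind == "drifting_bar":
        p.setdefault("speed_deg_s", 10.0)
        p.setdefault("moving_s", 4.0)
        p.setdefault("flank_s", 0.0)
        total = 2 * p["flank_s"] + p["moving_s"]
        t = np.arange(0.0, total + dt / 2, dt)
        pos = np.clip(t - p["flank_s"], 0.0, p["moving_s"]) * p["speed_deg_s"]
    else:
        raise ValueError(f"unknown stimulus kind: {kind}")
    vel = np.zeros_like(pos)
    vel[1:] = np.diff(pos) / dt
    return StimulusProfile(t=t, position=pos, velocity=vel, kind=kind,
                           params=p)


@dataclass
class SyntheticPopulationParams:
    """Configuration of the synthetic oDSGC populations.

    ``peak_spikes`` are mean preferred-direction responses (spikes per bar
    sweep) at full contrast; ``kappa`` the Von Mises width of each type's
    tuning (smaller = broader, so Superior is broader); ``contrast_scales``
    multiply the response amplitude per condition and
    ``low_contrast_sharpening`` multiplies κ under the reduced contrast
    (both cell types sharpen at low contrast). Trial noise is Poisson on
    spike counts by default; a negative-binomial alternative is selected by
    a finite ``dispersion`` (variance = mean + mean²/dispersion).
    """

    n_superior: int = 30
    n_inferior: int = 30
    peak_spikes: dict = field(default_factory=lambda: {
        "Superior": 20.0, "Inferior": 12.0})
    kappa: dict = field(default_factory=lambda: {
        "Superior": 1.3, "Inferior": 2.2})
    contrast_scales: dict = field(default_factory=lambda: {
        "high": 1.0, "low": 0.35})
    low_contrast_sharpening: float = 1.6
    pd_jitter_deg: float = 15.0
    n_trials: int = 5
    noise: str = "poisson"          # poisson | negative_binomial
    dispersion: float = np.inf      # negbin only; larger = closer to Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_superior <= 0 or self.n_inferior <= 0:
            raise ValueError("cell counts must be positive")
        if any(k <= 0 for k in self.kappa.values()):
            raise ValueError("kappa must be positive")
        if any(not (0 < s <= 1) for s in self.contrast_scales.values()):
            raise ValueError("contrast scale factors must lie in (0, 1]")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model: {self.noise}")


@dataclass
class SyntheticCell:
    cell_id: int
    cell_type: str     # Superior | Inferior
    contrast: str      # high | low
    response: DirectionalResponse
    true_pd_deg: float


def _draw_counts(rng: np.random.Generator, lam: np.ndarray,
                 params: SyntheticPopulationParams) -> np.ndarray:
    if params.noise == "poisson" or not np.isfinite(params.dispersion):
        return rng.poisson(lam).astype(float)
    # negative binomial with mean lam, variance lam + lam²/r
    r = params.dispersion
    p = r / (r + lam)
    return rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)).astype(float)


def make_population(params: SyntheticPopulationParams) -> list[SyntheticCell]:
    """Draw Superior and Inferior populations at both contrasts.

    Each cell's 8-direction mean rates follow a Von Mises-shaped profile
    peaked at the cell's preferred direction (the type axis plus Gaussian
    jitter); per-trial spike counts add the configured count noise, and the
    recorded tuning curve is the trial mean. The same cell (same preferred
    direction) is sampled at both contrasts, as in a within-cell contrast
    experiment.
    """
    rng = np.random.default_rng(params.seed)
    cells: list[SyntheticCell] = []
    cell_id = 0
    for cell_type, n in (("Superior", params.n_superior),
                         ("Inferior", params.n_inferior)):
        for _ in range(n):
            pd = (TYPE_PD_DEG[cell_type]
                  + rng.normal(0.0, params.pd_jitter_deg)) % 360.0
            for contrast in ("high", "low"):
                scale = params.contrast_scales[contrast]
                kappa = params.kappa[cell_type]
                if contrast == "low":
                    kappa *= params.low_contrast_sharpening
                lam = (params.peak_spikes[cell_type] * scale
                       * np.exp(kappa * (np.cos(np.deg2rad(
                           DIRECTIONS_8 - pd)) - 1.0)))
                trials = np.stack([_draw_counts(rng, lam, params)
                                   for _ in range(params.n_trials)])
                resp = DirectionalResponse(DIRECTIONS_8, trials.mean(axis=0),
                                           unit="spikes", trials=trials)
                cells.append(SyntheticCell(cell_id, cell_type, contrast,
                                           resp, pd))
            cell_id += 1
    return cells


def _alpha_kernel(t: np.ndarray, onset_s: float, tau_s: float) -> np.ndarray:
    """Unit-peak alpha function (t/τ)·exp(1 − t/τ) starting at onset."""
    s = np.maximum(t - onset_s, 0.0) / tau_s
    return s * np.exp(1.0 - s)


def make_conductance_set(cell_type: str = "Superior",
                         peak_ex_nS: float | None = None,
                         peak_in_nS: float = 4.0,
                         kappa_inhibition: float = 2.0,
                         duration_s: float = 3.0,
                         dt: float = 1e-3,
                         noise_sd: float = 0.0,
                         seed: int = 0,
                         **membrane) -> ConductanceSet:
    """Synthesize a per-direction conductance set for the membrane model.

    Inhibition follows a smooth alpha-shaped time course whose amplitude is
    weighted by an inverted Von Mises over direction: minimal in the
    preferred direction, maximal in the null. Excitation is a single
    untuned alpha kernel scaled by the cell-type excitatory gain — both
    cell types receive similar inhibition, but Superior cells receive
    larger excitation (default 1.2 vs 0.9 nS peak). Inhibition slightly
    leads excitation and reverses just below rest, so it acts mainly by
    shunting: membrane-potential tuning then scales near-proportionally
    with excitatory gain while spike tuning sharpens through the
    threshold, the dissociation the model exists to demonstrate.

    ``noise_sd`` adds seeded multiplicative smooth noise (fraction of the
    kernel amplitude); extra keyword arguments override membrane constants.
    """
    if peak_ex_nS is None:
        peak_ex_nS = {"Superior": 1.2, "Inferior": 0.9}[cell_type]
    if peak_ex_nS < 0 or peak_in_nS < 0:
        raise ValueError("conductance gains must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, dt)
    ex_kernel = _alpha_kernel(t, onset_s=0.5, tau_s=0.4)
    in_kernel = _alpha_kernel(t, onset_s=0.4, tau_s=0.45)
    pd = TYPE_PD_DEG[cell_type]
    nd = (pd + 180.0) % 360.0
    weights = np.exp(kappa_inhibition * (np.cos(np.deg2rad(
        DIRECTIONS_8 - nd)) - 1.0))
    g_in = peak_in_nS * weights[:, None] * in_kernel[None, :]
    g_ex = peak_ex_nS * ex_kernel
    if noise_sd > 0:
        # smooth seeded noise: low-pass filtered white noise per series
        def smooth_noise(n: int) -> np.ndarray:
            w = rng.normal(0.0, 1.0, n)
            k = np.hanning(101)
            return np.convolve(w, k / k.sum(), mode="same")
        g_ex = np.maximum(g_ex * (1 + noise_sd * smooth_noise(t.size)), 0.0)
        g_in = np.maximum(
            g_in * (1 + noise_sd * np.stack(
                [smooth_noise(t.size) for _ in range(8)])), 0.0)
    return ConductanceSet(dt=dt, g_in=g_in, g_ex=g_ex, **membrane)


def make_grating_rates(stimulus: StimulusProfile,
                       gain_superior_hz: float = 12.0,
                       gain_inferior_hz: float = 8.0,
                       baseline_hz: float = 0.5,
                       modulation_depth: float = 1.0,
                       noise_sd_hz: float = 0.0,
                       bin_s: float = 0.005,
                       seed: int = 0) -> dict:
    """Population firing rates of both oDSGC types over an oscillation.

    Each population's rate is a half-wave-rectified copy of the normalized
    stimulus velocity — Superior cells fire during the superior-motion
    half-cycle (positive velocity), Inferior during the other half — scaled
    by the population gain, on a 5 ms grid. Returns a dict with ``t``,
    ``superior``, and ``inferior`` arrays.
    """
    if stimulus.kind != "oscillating":
        raise ValueError("grating rates require an oscillating stimulus")
    t = np.arange(stimulus.t[0], stimulus.t[-1], bin_s)
    v = np.interp(t, stimulus.t, stimulus.velocity)
    vmax = np.abs(v).max()
    v_norm = v / vmax if vmax > 0 else v
    rng = np.random.default_rng(seed)
    out = {"t": t}
    for name, gain, sign in (("superior", gain_superior_hz, 1.0),
                             ("inferior", gain_inferior_hz, -1.0)):
        rate = baseline_hz + gain * modulation_depth * np.maximum(
            sign * v_norm, 0.0)
        if noise_sd_hz > 0:
            rate = rate + rng.normal(0.0, noise_sd_hz, t.size)
        out[name] = np.maximum(rate, 0.0)
    return out


@dataclass
class EyeTraceData:
    """Synthetic eye trace plus the ground truth used to build it."""

    t: np.ndarray               # s
    theta: np.ndarray           # degrees, positive = superior
    true_saccades: list         # (start_s, end_s) tuples
    params: dict


def make_eye_trace(stimulus: StimulusProfile,
                   slow_gain: float | dict = 0.6,
                   saccade_rate_hz: float = 0.25,
                   saccade_amp_deg: float = 5.0,
                   saccade_duration_s: float = 0.03,
                   drift_deg_s: float = 0.0,
                   noise_sd_deg_s: float = 0.0,
                   frame_rate_hz: float = 100.0,
                   seed: int = 0) -> EyeTraceData:
    """Simulate a vertical eye-position trace tracking a stimulus.

    Slow-phase velocity is ``slow_gain`` × stimulus velocity (a dict
    ``{"superior": g1, "inferior": g2}`` applies stage-specific gains by
    stimulus-velocity sign) plus constant drift and white velocity noise.
    Resetting saccades are inserted at Poisson times as brief high-velocity
    displacements directed back toward the neutral position; their
    ground-truth intervals are returned.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    if noise_sd_deg_s < 0:
        raise ValueError("noise SD must be non-negative")
    dt = 1.0 / frame_rate_hz
    t = np.arange(stimulus.t[0], stimulus.t[-1] + dt / 2, dt)
    stim_v = np.interp(t, stimulus.t, stimulus.velocity)
    rng = np.random.default_rng(seed)
    if isinstance(slow_gain, dict):
        gain = np.where(stim_v >= 0, slow_gain.get("superior", 0.0),
                        slow_gain.get("inferior", 0.0))
    else:
        gain = float(slow_gain)
    vel = gain * stim_v + drift_deg_s
    if noise_sd_deg_s > 0:
        vel = vel + rng.normal(0.0, noise_sd_deg_s, t.size)

    # Poisson saccade times within the trace span
    saccades: list[tuple[float, float]] = []
    n_sacc_samples = max(int(round(saccade_duration_s / dt)), 1)
    if saccade_rate_hz > 0:
        time = float(t[0]) + rng.exponential(1.0 / saccade_rate_hz)
        while time < t[-1] - saccade_duration_s:
            saccades.append((time, time + saccade_duration_s))
            time += saccade_duration_s + rng.exponential(1.0 / saccade_rate_hz)

    theta = np.concatenate(([0.0], np.cumsum(vel[1:]) * dt))
    for (s0, s1) in saccades:
        i0 = int(np.searchsorted(t, s0))
        i1 = min(i0 + n_sacc_samples, t.size - 1)
        amp = saccade_amp_deg * (1 + 0.2 * rng.standard_normal())
        # resetting: jump back toward 0°, or a random sign near neutral
        here = theta[i0]
        sign = -np.sign(here) if abs(here) > 0.5 else rng.choice([-1.0, 1.0])
        jump = sign * abs(amp)
        per_step = jump / (i1 - i0)
        theta[i0:i1] += np.cumsum(np.full(i1 - i0, per_step))
        theta[i1:] += jump
    return EyeTraceData(t=t, theta=theta, true_saccades=saccades,
                        params={"slow_gain": slow_gain,
                                "saccade_rate_hz": saccade_rate_hz,
                                "drift_deg_s": drift_deg_s,
                                "noise_sd_deg_s": noise_sd_deg_s,
                                "frame_rate_hz": frame_rate_hz,
                                "seed": seed})
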