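"""Direction-tuning statistics for ON direction-selective retinal ganglion cells.

All metrics operate on 8-direction tuning curves sampled at 45° spacing in
retinal coordinates. The central quantities are the vector-sum preferred
direction, the direction selectivity index (DSI: vector-sum magnitude over
scalar sum), linear and normalized tuning-curve areas (circular trapezoidal
integrals divided by 360°), the width at a fractional response level, and a
least-squares Von Mises fit.

Zero-spike conventions (applied when every direction evokes zero spikes):
DSI = 1, linear area = 0, normalized area = 0. They encode the empirical
limit in which a cell's last remaining spikes are confined to the preferred
direction. The conventions apply to spike curves only; subthreshold-voltage
curves with no deflection are degenerate and raise instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import least_squares
from scipy.special import i0, i0e

__all__ = [
    "DirectionalResponse",
    "VonMisesFit",
    "RetinalAxes",
    "CellClass",
    "preferred_direction",
    "direction_selectivity_index",
    "linear_tuning_area",
    "normalize_curve",
    "normalized_area",
    "width_at_fraction",
    "fit_von_mises",
    "von_mises",
    "classify_odsgc",
    "UndefinedDirectionError",
]

DIRECTIONS_8 = np.arange(0.0, 360.0, 45.0)


class UndefinedDirectionError(ValueError):
    """Raised when a preferred direction cannot be defined (zero vector sum)."""


@dataclass
class DirectionalResponse:
    """Responses of one cell to 8 motion directions.

    Parameters
    ----------
    directions : array of 8 angles in degrees on [0, 360), 45° apart, sorted.
    mean_response : non-negative response per direction. Units are carried in
        ``unit`` (spikes, spikes/s, mV, pA, or an E/I ratio).
    trials : optional (n_trials, 8) per-trial responses whose column means
        must equal ``mean_response``.
    """

    directions: np.ndarray
    mean_response: np.ndarray
    unit: str = "spikes"
    trials: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.mean_response = np.asarray(self.mean_response, dtype=float)
        if self.directions.shape != (8,) or self.mean_response.shape != (8,):
            raise ValueError("expected 8 directions and 8 mean responses")
        if not np.all(np.diff(self.directions) == 45.0):
            raise ValueError("directions must be sorted with 45° spacing")
        if np.any(self.mean_response < 0):
            raise ValueError("mean responses must be non-negative")
        if self.trials is not None:
            self.trials = np.asarray(self.trials, dtype=float)
            if self.trials.ndim != 2 or self.trials.shape[1] != 8:
                raise ValueError("trials must be (n_trials, 8)")
            if not np.allclose(self.trials.mean(axis=0), self.mean_response,
                               atol=1e-9):
                raise ValueError("trial means must match mean_response")

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.mean_response == 0))


@dataclass
class VonMisesFit:
    """Result of fitting amplitude·exp(κ·cos(x−μ))/(2π·I0(κ))."""

    mu: float          # curve center, degrees
    kappa: float       # width parameter; larger = sharper
    amplitude: float   # multiplicative scale, response units
    sse: float         # sum of squared residuals

    def __call__(self, degrees: np.ndarray | float) -> np.ndarray | float:
        return von_mises(degrees, self.mu, self.kappa, self.amplitude)


class CellClass(str, Enum):
    SUPERIOR = "Superior"
    INFERIOR = "Inferior"
    EXCLUDED = "excluded"


@dataclass
class RetinalAxes:
    """Anatomical axis frame in retinal coordinates.

    Angles are the directions (degrees) of motion *toward* each pole.
    Superior oDSGCs prefer dorsal-to-ventral motion on the retina, i.e. a
    preferred direction with a component toward the ventral pole.
    """

    nasal_deg: float = 0.0
    dorsal_deg: float = 90.0

    @property
    def ventral_deg(self) -> float:
        return (self.dorsal_deg + 180.0) % 360.0


def _vector_sum(resp: DirectionalResponse) -> complex:
    ang = np.deg2rad(resp.directions)
    return complex(np.sum(resp.mean_response * np.exp(1j * ang)))


def preferred_direction(resp: DirectionalResponse) -> float:
    """Direction of the vector sum of the 8 responses, degrees on [0, 360).

    This is the resultant of unit vectors weighted by the per-direction
    responses, not necessarily the probed direction with the largest
    response.
    """
    if resp.is_zero:
        raise UndefinedDirectionError("all responses are zero")
    z = _vector_sum(resp)
    if abs(z) < 1e-12 * resp.mean_response.sum():
        raise UndefinedDirectionError("vector sum has zero magnitude")
    deg = float(np.rad2deg(np.angle(z)) % 360.0)
    return 0.0 if deg >= 360.0 else deg  # −ε % 360 rounds up to 360.0


def direction_selectivity_index(resp: DirectionalResponse) -> float:
    """|vector sum| / scalar sum, in [0, 1]; all-zero spike curves return 1."""
    total = resp.mean_response.sum()
    if total == 0:
        return 1.0  # zero-spike convention
    return float(abs(_vector_sum(resp)) / total)


def _circular_trapezoid(directions: np.ndarray, values: np.ndarray) -> float:
    """Area under the closed tuning curve (wraps 315°→360°≡0°)."""
    d = np.append(directions, directions[0] + 360.0)
    v = np.append(values, values[0])
    return float(np.trapezoid(v, d))


def linear_tuning_area(resp: DirectionalResponse) -> float:
    """Circular trapezoidal area under the linear tuning curve / 360°.

    All-zero spike curves return 0 by convention.
    """
    if resp.is_zero:
        return 0.0
    return _circular_trapezoid(resp.directions, resp.mean_response) / 360.0


def _interp_at(resp: DirectionalResponse, angle_deg: float) -> float:
    """Linear-in-angle interpolation of the curve at an arbitrary angle."""
    d = np.append(resp.directions, resp.directions[0] + 360.0)
    v = np.append(resp.mean_response, resp.mean_response[0])
    return float(np.interp(angle_deg % 360.0, d, v))


def normalize_curve(resp: DirectionalResponse) -> DirectionalResponse:
    """Divide all responses by the (interpolated) preferred-direction response.

    When the vector-sum preferred direction falls between probed directions
    the normalizing response is linearly interpolated between the two
    flanking probed directions.
    """
    pd = preferred_direction(resp)
    pd_resp = _interp_at(resp, pd)
    if pd_resp <= 0:
        raise ZeroDivisionError(
            "interpolated preferred-direction response is zero")
    return DirectionalResponse(
        directions=resp.directions.copy(),
        mean_response=resp.mean_response / pd_resp,
        unit="normalized",
    )


def normalized_area(resp: DirectionalResponse) -> float:
    """Area of the preferred-direction-normalized curve / 360°.

    1 for a perfectly circular (uniform) curve; larger values mean wider
    curves. All-zero spike curves return 0 by convention.
    """
    if resp.is_zero:
        return 0.0
    try:
        norm = normalize_curve(resp)
    except UndefinedDirectionError:
        if np.ptp(resp.mean_response) == 0:
            return 1.0  # perfectly circular: every direction is preferred
        raise
    return _circular_trapezoid(norm.directions, norm.mean_response) / 360.0


def width_at_fraction(resp: DirectionalResponse,
                      fraction: float = 0.5) -> tuple[float, bool]:
    """Angular width of the region around the preferred direction where the
    normalized response stays ≥ ``fraction``.

    Returns ``(width_deg, saturated)``; ``saturated`` is True when the curve
    never drops below the fraction (width 360°). Crossings are located by
    linear interpolation on the piecewise-linear closed curve, taking the
    crossing nearest the preferred direction on each side.
    """
    if fraction <= 0:
        return 360.0, True
    norm = normalize_curve(resp)
    pd = preferred_direction(resp)

    def level(offset: float) -> float:
        return _interp_at(norm, pd + offset)

    if norm.mean_response.min() >= fraction:
        # closed curve is piecewise linear between nodes, so the minimum
        # over the whole circle is attained at a probed direction
        return 360.0, True

    def crossing(sign: int) -> float:
        # walk node-to-node away from the PD; the curve is linear on each
        # segment, so the first crossing is solved exactly. Offsets of the
        # probed nodes from the PD, in the walk direction:
        offs = sorted({(sign * (d - pd)) % 360.0
                       for d in norm.directions} - {0.0})
        prev_off, prev_val = 0.0, level(0.0)
        for off in list(offs) + [360.0]:
            val = level(sign * off)
            if prev_val >= fraction > val:
                t = (prev_val - fraction) / (prev_val - val)
                return prev_off + t * (off - prev_off)
            prev_off, prev_val = off, val
        return 180.0

    return float(crossing(+1) + crossing(-1)), False


def von_mises(degrees: np.ndarray | float, mu: float, kappa: float,
              amplitude: float = 1.0) -> np.ndarray | float:
    """amplitude · exp(κ·cos(x−μ)) / (2π·I0(κ)), angles in degrees."""
    x = np.deg2rad(np.asarray(degrees, dtype=float) - mu)
    # exp(κ·cosx)/I0(κ) = exp(κ·(cosx−1))/i0e(κ): stable for large κ
    out = amplitude * np.exp(kappa * (np.cos(x) - 1.0)) / (
        2.0 * np.pi * i0e(kappa))
    return out if np.ndim(degrees) else float(out)


def fit_von_mises(resp: DirectionalResponse) -> VonMisesFit:
    """Least-squares Von Mises fit with a free amplitude multiplier.

    Deterministic multi-start: μ initialized at each of the 8 probed
    directions, κ at {0.5, 2, 8}, amplitude from the implied peak. The best
    (lowest SSE) converged solution wins; exact ties keep the first start.
    """
    if np.count_nonzero(resp.mean_response) < 3:
        raise ValueError("need at least 3 non-zero responses to fit")
    x = resp.directions
    y = resp.mean_response

    def residuals(p: np.ndarray) -> np.ndarray:
        mu, log_kappa, log_amp = p
        return von_mises(x, mu, np.exp(log_kappa), np.exp(log_amp)) - y

    best = None
    for mu0 in x:
        for kappa0 in (0.5, 2.0, 8.0):
            peak = max(y.max(), 1e-9)
            amp0 = peak * 2.0 * np.pi * i0(kappa0) / np.exp(kappa0)
            p0 = np.array([mu0, np.log(kappa0), np.log(amp0)])
            try:
                sol = least_squares(residuals, p0, method="lm", xtol=1e-14,
                                    ftol=1e-14, max_nfev=2000)
            except Exception:
                continue
            sse = float(np.sum(sol.fun ** 2))
            if best is None or sse < best[0] - 1e-15:
                best = (sse, sol.x)
    if best is None:
        raise RuntimeError("Von Mises fit failed to converge from any start")
    sse, (mu, log_kappa, log_amp) = best
    return VonMisesFit(mu=float(mu % 360.0), kappa=float(np.exp(log_kappa)),
                       amplitude=float(np.exp(log_amp)), sse=sse)


def classify_odsgc(resp: DirectionalResponse,
                   axes: RetinalAxes | None = None,
                   dsi_threshold: float = 0.05,
                   axis_margin_deg: float = 30.0) -> CellClass:
    """Classify a cell as Superior, Inferior, or excluded.

    A cell is retained when its DSI exceeds ``dsi_threshold`` and its
    preferred direction lies more than ``axis_margin_deg`` away from the
    temporal-nasal axis; it is Superior when the preferred direction has a
    dorsal-to-ventral retinal component (toward the ventral pole), Inferior
    otherwise.
    """
    axes = axes or RetinalAxes()
    try:
        pd = preferred_direction(resp)
    except UndefinedDirectionError:
        return CellClass.EXCLUDED
    if direction_selectivity_index(resp) <= dsi_threshold:
        return CellClass.EXCLUDED
    # angular distance to the temporal-nasal axis (a line: both senses)
    d1 = abs((pd - axes.nasal_deg + 180.0) % 360.0 - 180.0)
    dist_to_axis = min(d1, 180.0 - d1)
    if dist_to_axis <= axis_margin_deg:
        return CellClass.EXCLUDED
    ventral_component = np.cos(np.deg2rad(pd - axes.ventral_deg))
    return CellClass.SUPERIOR if ventral_component > 0 else CellClass.INFERIOR
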