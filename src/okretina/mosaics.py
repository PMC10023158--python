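"""Retinal mosaic simulation and density recovery profiles.

A homotypic retinal ganglion cell type tiles the retina as a mosaic: somata
never overlap, and same-type neighbors obey a noisy exclusion zone set by
the type's coverage. The density recovery profile (DRP) — neighbor density
as a function of distance from each cell — therefore shows a dip near zero
distance for a single mosaic. A field pooled from k independent mosaics
fills that dip progressively, because cross-type pairs are only constrained
by soma size; the DRP of a pooled field is the signature used to decide how
many cell types a labeled population comprises.

Also included: retina center/radius estimation from perimeter points
(median circumcenter/circumradius over all point triples) and normalized
polar retinal coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MosaicField",
    "DensityRecoveryProfile",
    "generate_mosaics",
    "density_recovery_profile",
    "estimate_center_radius",
    "normalize_coordinates",
    "denormalize_coordinates",
    "MosaicPlacementError",
]


class MosaicPlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all requested cells."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed} of {requested} cells within the retry "
            f"budget; lower the density or the exclusion radius")


@dataclass
class MosaicField:
    """Cell positions (µm) within a circular model retina."""

    positions: np.ndarray          # (n, 2) µm
    mosaic_id: np.ndarray          # (n,) int
    retina_radius: float           # µm
    soma_radius: float = 15.0      # µm
    center: tuple = (0.0, 0.0)

    @property
    def n_cells(self) -> int:
        return int(self.positions.shape[0])

    @property
    def area_mm2(self) -> float:
        return float(np.pi * (self.retina_radius / 1000.0) ** 2)


@dataclass
class DensityRecoveryProfile:
    bin_edges: np.ndarray          # µm
    density: np.ndarray            # cells/mm² per annulus
    mean_density: float            # cells/mm² over the whole field
    counts: np.ndarray | None = None  # raw pair counts per annulus

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _regular_spacing_um(n_cells: int, retina_radius_um: float) -> float:
    """Nearest-neighbor spacing of a hexagonal mosaic at the coverage
    implied by n cells on the retina disc: d = sqrt(2 / (√3·λ))."""
    lam = n_cells / (np.pi * retina_radius_um ** 2)
    return float(np.sqrt(2.0 / (np.sqrt(3.0) * lam)))


def generate_mosaics(n_mosaics: int = 1,
                     total_cells: int = 669,
                     retina_radius_um: float = 2000.0,
                     soma_radius_um: float = 15.0,
                     exclusion_scale: float = 0.5,
                     exclusion_noise_sd: float = 0.15,
                     retry_budget: int = 10_000,
                     seed: int = 0) -> MosaicField:
    """Sequential rejection sampling of k overlaid mosaics.

    Every pair of cells must be at least two soma radii apart (monolayer
    non-overlap). Same-mosaic pairs additionally obey a noisy exclusion
    zone: for each candidate placement an exclusion distance is drawn as
    Normal(d̄, sd·d̄) around d̄ = ``exclusion_scale`` × the regular-mosaic
    spacing at that mosaic's coverage, floored at the soma diameter. Cells
    are divided as evenly as possible across mosaics so the grand total
    matches ``total_cells``. Placement order is randomized; a cell that
    cannot be placed within ``retry_budget`` attempts raises
    :class:`MosaicPlacementError`.
    """
    if n_mosaics < 1 or total_cells < 1:
        raise ValueError("need at least one mosaic and one cell")
    rng = np.random.default_rng(seed)
    base, extra = divmod(total_cells, n_mosaics)
    counts = [base + (1 if i < extra else 0) for i in range(n_mosaics)]
    spacing = {m: _regular_spacing_um(counts[m], retina_radius_um)
               for m in range(n_mosaics)}
    order = rng.permutation(np.repeat(np.arange(n_mosaics), counts))
    hard = 2.0 * soma_radius_um
    placed_xy: list[np.ndarray] = []
    placed_id: list[int] = []
    for i, m in enumerate(order):
        ok = False
        for _ in range(retry_budget):
            r = retina_radius_um * np.sqrt(rng.random())
            ang = 2.0 * np.pi * rng.random()
            p = np.array([r * np.cos(ang), r * np.sin(ang)])
            if placed_xy:
                d = np.linalg.norm(np.asarray(placed_xy) - p, axis=1)
                if np.any(d < hard):
                    continue
                same = np.asarray(placed_id) == m
                if same.any():
                    excl = max(spacing[m] * exclusion_scale
                               * (1.0 + exclusion_noise_sd
                                  * rng.standard_normal()), hard)
                    if np.any(d[same] < excl):
                        continue
            placed_xy.append(p)
            placed_id.append(int(m))
            ok = True
            break
        if not ok:
            raise MosaicPlacementError(i, total_cells)
    return MosaicField(positions=np.asarray(placed_xy),
                       mosaic_id=np.asarray(placed_id, dtype=int),
                       retina_radius=retina_radius_um,
                       soma_radius=soma_radius_um)


def _disc_circle_intersection_area(d: float, r: float, R: float) -> float:
    """Area of the intersection of a circle of radius r centered at
    distance d from the origin with the disc of radius R at the origin
    (classical two-circle lens formula)."""
    if d >= r + R:
        return 0.0
    if d <= abs(R - r):
        return float(np.pi * min(r, R) ** 2)
    a1 = r ** 2 * np.arccos((d ** 2 + r ** 2 - R ** 2) / (2 * d * r))
    a2 = R ** 2 * np.arccos((d ** 2 + R ** 2 - r ** 2) / (2 * d * R))
    a3 = 0.5 * np.sqrt((-d + r + R) * (d + r - R) * (d - r + R) * (d + r + R))
    return float(a1 + a2 - a3)


def density_recovery_profile(positions: np.ndarray,
                             retina_radius_um: float,
                             bin_um: float = 10.0,
                             max_um: float = 150.0,
                             edge_correction: str = "clip",
                             center: tuple = (0.0, 0.0),
                             ) -> DensityRecoveryProfile:
    """Neighbor density versus distance (Rodieck-style DRP).

    For every reference cell, neighbors are counted in concentric annuli;
    counts are divided by the summed annulus areas over reference cells.
    With ``edge_correction="clip"`` each annulus area is clipped to the
    retina disc (exact circular-segment geometry); ``"none"`` uses full
    annulus areas, biased low near the field edge. Densities are cells/mm².
    """
    if bin_um <= 0:
        raise ValueError("bin width must be positive")
    if edge_correction not in ("clip", "none"):
        raise ValueError(f"unknown edge correction: {edge_correction}")
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 points")
    edges = np.arange(0.0, max_um + bin_um / 2, bin_um)
    n = pos.shape[0]
    dmat = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    dists = dmat[~np.eye(n, dtype=bool)]
    counts, _ = np.histogram(dists, bins=edges)
    areas_um2 = np.zeros(edges.size - 1)
    if edge_correction == "none":
        ring = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        areas_um2 = n * ring
    else:
        cdist = np.linalg.norm(pos - np.asarray(center), axis=1)
        for i in range(n):
            caps = [_disc_circle_intersection_area(cdist[i], e,
                                                   retina_radius_um)
                    for e in edges]
            areas_um2 += np.diff(caps)
    density = counts / (areas_um2 * 1e-6)  # µm² → mm²
    mean_density = n / (np.pi * (retina_radius_um / 1000.0) ** 2)
    return DensityRecoveryProfile(bin_edges=edges, density=density,
                                  mean_density=float(mean_density),
                                  counts=counts)


def _circumcircle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                  ) -> tuple[np.ndarray, float] | None:
    """Circumcenter and circumradius of a triangle; None when degenerate."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    scale = max(np.abs([ax, ay, bx, by, cx, cy]).max(), 1.0)
    if abs(d) < 1e-12 * scale ** 2:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(center - p1))


def estimate_center_radius(perimeter_points: np.ndarray) -> dict:
    """Estimate a retina's center and radius from perimeter points.

    Enumerates all unique triples of the (≥ 8) perimeter points, computes
    each triple's circumcenter and circumradius, and returns the
    componentwise median center and the median radius; degenerate
    (collinear) triples are skipped.
    """
    pts = np.asarray(perimeter_points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 perimeter points")
    centers = []
    radii = []
    for i, j, k in itertools.combinations(range(pts.shape[0]), 3):
        res = _circumcircle(pts[i], pts[j], pts[k])
        if res is not None:
            centers.append(res[0])
            radii.append(res[1])
    if not centers:
        raise ValueError("all point triples are degenerate (collinear)")
    centers = np.asarray(centers)
    return {"center": (float(np.median(centers[:, 0])),
                       float(np.median(centers[:, 1]))),
            "radius": float(np.median(radii))}


def normalize_coordinates(positions: np.ndarray, center: tuple,
                          radius: float,
                          dorsal_axis_deg: float = 90.0) -> np.ndarray:
    """Map positions to normalized polar retinal coordinates.

    Returns (n, 2) array of (r, angle_deg): r is distance from the center
    divided by the retina radius (1 on the perimeter), angle is measured
    from the dorsal axis, counterclockwise, in degrees on [0, 360).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rel = np.atleast_2d(np.asarray(positions, dtype=float)) - np.asarray(center)
    r = np.linalg.norm(rel, axis=1) / radius
    ang = (np.rad2deg(np.arctan2(rel[:, 1], rel[:, 0]))
           - dorsal_axis_deg) % 360.0
    ang[r == 0] = 0.0
    return np.column_stack([r, ang])


def denormalize_coordinates(polar: np.ndarray, center: tuple, radius: float,
                            dorsal_axis_deg: float = 90.0) -> np.ndarray:
    """Inverse of :func:`normalize_coordinates`."""
    polar = np.atleast_2d(np.asarray(polar, dtype=float))
    ang = np.deg2rad(polar[:, 1] + dorsal_axis_deg)
    xy = radius * polar[:, 0, None] * np.column_stack(
        [np.cos(ang), np.sin(ang)])
    return xy + np.asarray(center)
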