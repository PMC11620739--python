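"""Population geometry: the two analyzed point clouds and the spatial
configuration of one-dimensional attractors.

The population matrix M (n_grid x 625 cropped pixels) defines two point
clouds: its columns (population activity vectors per pixel, analyzed with the
kNN-geodesic metric) and its rows (per-neuron maps, analyzed with the Pearson
correlation distance).

For ring-attractor networks, each pixel can additionally be assigned the ring
coordinate best describing the population vector there (circular mean of the
neuron coordinates weighted by activity).  Because every ring coordinate must
reappear with hexagonal periodicity in space, one full cycle of the attractor
corresponds to a spatial displacement by some lattice vector: its hexagonal
neighbor order is the configuration order O_n (O_0 when the cycle closes
within a single field).  The order is measured from the unwrapped phase
increment per primitive lattice vector: if translating by a_1/a_2 advances
the ring phase by delta_1/delta_2, the attractor cycle displacement is the
minimal-order integer combination m a_1 + k a_2 with
m delta_1 + k delta_2 = 2 pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .config import CROP_SLICE, PIXEL_SIZE
from .gridmetrics import (detect_maxima, estimate_spacing,
                          population_autocorrelogram)
from .topology import PointCloud

__all__ = [
    "crop_maps", "population_matrix",
    "build_population_cloud", "build_neuron_cloud",
    "attractor_phase_map", "frontier_mask", "grid_geometry",
    "configuration_order", "configuration_order_from_maps", "stripe_order",
    "ConfigurationReport",
]


def crop_maps(maps: np.ndarray) -> np.ndarray:
    """Central 60 cm square (25 x 25 pixels) of each 1 m map."""
    return maps[:, CROP_SLICE, CROP_SLICE]


def population_matrix(maps: np.ndarray) -> np.ndarray:
    """M[i, j]: mean activity of neuron i in cropped pixel j (625 columns)."""
    c = crop_maps(maps)
    return c.reshape(c.shape[0], -1)


def build_population_cloud(maps: np.ndarray, k: int = 10) -> PointCloud:
    """Columns of M as points in R^{n_grid}, kNN-geodesic metric (k=10)."""
    M = population_matrix(maps)
    pts = M.T
    if np.allclose(pts, 0):
        raise ValueError("all-zero rate maps give a degenerate cloud")
    return PointCloud(pts, metric="knn_geodesic", k=k,
                      provenance="population")


def build_neuron_cloud(maps: np.ndarray) -> PointCloud:
    """Rows of M as points in R^625, Pearson-correlation metric."""
    M = population_matrix(maps)
    if np.allclose(M, 0):
        raise ValueError("all-zero rate maps give a degenerate cloud")
    return PointCloud(M, metric="pearson_correlation", provenance="neurons")


# ---------------------------------------------------------------------------
# attractor phase maps (computed on the full 41 x 41 maps: the lattice-vector
# paths below need more room than the 25-pixel central crop)
# ---------------------------------------------------------------------------

def attractor_phase_map(maps: np.ndarray, architecture: str):
    """Attractor coordinate of the population center of mass, per pixel.

    Ring: neurons sit at angles 2 pi c / n; each pixel gets the circular mean
    of the neuron angles weighted by activity; pixels with a degenerate
    resultant (e.g. two balanced antipodal bumps) are flagged invalid.
    Stripe: linear weighted mean of the neuron positions 0..1.

    Returns (phase_map, valid_mask); phase in radians for rings, in [0, 1]
    for stripes; maps keep the full 41 x 41 pixel grid.
    """
    X = maps.reshape(maps.shape[0], -1)
    n = X.shape[0]
    shape = maps.shape[1:]
    if architecture in ("ring1d", "ring"):
        ang = 2 * np.pi * np.arange(n) / n
        z = (X * np.exp(1j * ang)[:, None]).sum(0)
        tot = X.sum(0)
        with np.errstate(invalid="ignore", divide="ignore"):
            resultant = np.abs(z) / np.where(tot > 1e-12, tot, np.nan)
        phase = np.angle(z) % (2 * np.pi)
        valid = np.isfinite(resultant) & (resultant > 1e-3)
        return phase.reshape(shape), valid.reshape(shape)
    if architecture in ("stripe1dl", "stripe"):
        pos = np.arange(n) / max(n - 1, 1)
        tot = X.sum(0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = (X * pos[:, None]).sum(0) / tot
        valid = tot > 1e-12
        return np.where(valid, mean, 0.0).reshape(shape), valid.reshape(shape)
    raise ValueError(
        f"phase maps are defined for 1D architectures, not {architecture!r}")


def frontier_mask(phase_map: np.ndarray,
                  threshold: float = np.pi / 4) -> np.ndarray:
    """Pixels of abrupt circular phase change (visualization aid)."""
    def circ_diff(a, b):
        return np.angle(np.exp(1j * (a - b)))
    gx = np.zeros_like(phase_map)
    gy = np.zeros_like(phase_map)
    gx[1:] = circ_diff(phase_map[1:], phase_map[:-1])
    gy[:, 1:] = circ_diff(phase_map[:, 1:], phase_map[:, :-1])
    return np.hypot(gx, gy) > threshold


@dataclass
class ConfigurationReport:
    order: int | None
    phase_map: np.ndarray
    frontiers: np.ndarray
    resolved: bool
    detail: str = ""


@dataclass
class GridGeometry:
    spacing: float       # cm
    orientation: float   # radians, first lattice axis
    flagged: bool

    @property
    def lattice_vectors_px(self) -> tuple[np.ndarray, np.ndarray]:
        s = self.spacing / PIXEL_SIZE
        a1 = s * np.array([np.cos(self.orientation),
                           np.sin(self.orientation)])
        a2 = s * np.array([np.cos(self.orientation + np.pi / 3),
                           np.sin(self.orientation + np.pi / 3)])
        return a1, a2


def grid_geometry(maps: np.ndarray) -> GridGeometry:
    """Shared lattice spacing and orientation of an aligned population, from
    the population autocorrelogram and its first-order maxima."""
    pac = population_autocorrelogram(maps)
    spacing, flagged = estimate_spacing(pac)
    mx = detect_maxima(pac, spacing)
    if len(mx) < 2:
        return GridGeometry(spacing, 0.0, True)
    ang = np.rad2deg(np.arctan2(mx[:, 1], mx[:, 0])) % 60
    # circular median on the 60-degree cycle
    z = np.exp(1j * np.deg2rad(ang * 6)).mean()
    orientation = np.deg2rad((np.rad2deg(np.angle(z)) / 6) % 60)
    return GridGeometry(spacing, orientation, flagged)


# ---------------------------------------------------------------------------
# configuration order (ring)
# ---------------------------------------------------------------------------

def _phase_increment(phase_map: np.ndarray, start: np.ndarray,
                     vec: np.ndarray, n_samples: int = 64):
    """Unwrapped circular phase change along the straight path start ->
    start + vec (pixel coordinates).  Returns (increment, ok); not ok when a
    single sampling step jumps more than half a cycle."""
    t = np.linspace(0.0, 1.0, n_samples + 1)
    pts = start[None] + vec[None] * t[:, None]
    cs = map_coordinates(np.cos(phase_map), pts.T, order=1, mode="nearest")
    sn = map_coordinates(np.sin(phase_map), pts.T, order=1, mode="nearest")
    ph = np.arctan2(sn, cs)
    d = np.angle(np.exp(1j * np.diff(ph)))
    if np.any(np.abs(d) > np.pi * 0.9):
        return 0.0, False
    return float(d.sum()), True


def _lattice_increments(phase_map: np.ndarray, geom: GridGeometry):
    """Median unwrapped phase increment per primitive lattice vector,
    measured over a grid of anchor pixels whose paths stay inside the map."""
    a1, a2 = geom.lattice_vectors_px
    side = phase_map.shape[0]
    anchors = []
    margin = 1.0
    for x in np.linspace(2, side - 3, 7):
        for y in np.linspace(2, side - 3, 7):
            anchors.append(np.array([x, y]))
    out = []
    for vec in (a1, a2):
        vals = []
        for s in anchors:
            e = s + vec
            if (min(s.min(), e.min()) < margin
                    or max(s.max(), e.max()) > side - 1 - margin):
                continue
            inc, ok = _phase_increment(phase_map, s, vec)
            if ok:
                vals.append(inc)
        if not vals:
            return None
        out.append(float(np.median(vals)))
    return out


def configuration_order(phase_map: np.ndarray,
                        geom: GridGeometry,
                        max_order: int = 6,
                        tol: float = 0.2) -> ConfigurationReport:
    """Configuration order O_n of a ring phase map.

    Measures the unwrapped phase increments (delta_1, delta_2) per primitive
    lattice vector and finds the integer combination (m, k), bounded by
    `max_order`, with m delta_1 + k delta_2 = 2 pi and minimal hexagonal
    neighbor order; that order is O_n.  Near-zero increments mean the
    attractor cycle closes inside one field: O_0.  Reports unresolvable when
    phase unwrapping fails or no integer combination matches.
    """
    fr = frontier_mask(phase_map)
    incs = _lattice_increments(phase_map, geom)
    if incs is None:
        return ConfigurationReport(None, phase_map, fr, False,
                                   "phase unwrapping failed on all paths")
    d1, d2 = incs
    if abs(d1) < 0.3 and abs(d2) < 0.3:
        return ConfigurationReport(0, phase_map, fr, True,
                                   f"increments ({d1:+.2f}, {d2:+.2f})")
    best = None
    for m in range(-max_order, max_order + 1):
        for k in range(-max_order, max_order + 1):
            res = m * d1 + k * d2 - 2 * np.pi
            if abs(res) < tol * 2 * np.pi:
                order = (abs(m) + abs(k) + abs(m + k)) // 2
                if order and (best is None or (order, abs(res)) <
                              (best[0], abs(best[3]))):
                    best = (order, m, k, res)
    if best is None:
        return ConfigurationReport(None, phase_map, fr, False,
                                   f"increments ({d1:+.2f}, {d2:+.2f}) match "
                                   "no lattice combination")
    order, m, k, res = best
    return ConfigurationReport(int(order), phase_map, fr, True,
                               f"cycle = {m} a1 + {k} a2, "
                               f"residual {res / (2 * np.pi):+.3f} cycles")


def configuration_order_from_maps(maps: np.ndarray) -> ConfigurationReport:
    """Convenience pipeline: ring phase map + lattice geometry + order."""
    phase, _ = attractor_phase_map(maps, "ring1d")
    geom = grid_geometry(maps)
    if geom.flagged:
        return ConfigurationReport(None, phase, frontier_mask(phase), False,
                                   "no reliable grid spacing")
    return configuration_order(phase, geom)


# ---------------------------------------------------------------------------
# stripe order
# ---------------------------------------------------------------------------

def stripe_order(maps: np.ndarray,
                 extreme_fraction: float = 0.1) -> ConfigurationReport:
    """Hexagonal neighbor order between the fields of the two stripe extremes.

    Pixels dominated by the first/last `extreme_fraction` of neurons are
    located; the displacement between the two groups' activity peaks
    (reduced to the lattice) gives the neighbor order: 0 when the extremes
    share a field, 1 when one lattice vector apart, etc.
    """
    phase, _ = attractor_phase_map(maps, "stripe1dl")
    geom = grid_geometry(maps)
    fr = frontier_mask(2 * np.pi * phase)
    if geom.flagged:
        return ConfigurationReport(None, phase, fr, False,
                                   "no reliable grid spacing")
    X = maps.reshape(maps.shape[0], -1)
    n = X.shape[0]
    k = max(int(extreme_fraction * n), 1)
    lo = X[:k].mean(0)
    hi = X[-k:].mean(0)
    shape = maps.shape[1:]
    p_lo = np.array(np.unravel_index(np.argmax(lo), shape), float)
    p_hi = np.array(np.unravel_index(np.argmax(hi), shape), float)
    a1, a2 = geom.lattice_vectors_px
    A = np.c_[a1, a2]
    mn = np.linalg.solve(A, p_hi - p_lo)
    m, kk = np.round(mn).astype(int)
    resid = np.linalg.norm(A @ (mn - np.round(mn))) * PIXEL_SIZE
    if resid > 0.35 * geom.spacing:
        return ConfigurationReport(None, phase, fr, False,
                                   f"extremes off-lattice by {resid:.1f} cm")
    order = int((abs(m) + abs(kk) + abs(m + kk)) // 2)
    return ConfigurationReport(order, phase, fr, True,
                               f"extreme displacement = {m} a1 + {kk} a2")
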