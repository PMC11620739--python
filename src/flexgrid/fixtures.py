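"""Synthetic generators with the structure the analyses assume.

Two families:

* :func:`ideal_grid_population` builds rate-map stacks of an aligned grid-cell
  population from the ideal three-cosine grid kernel, with spatial phases laid
  out either uniformly over the hexagonal unit cell (the end state of a
  2D-attractor-aligned network, whose population activity is a torus) or along
  a closed 1-cycle with a chosen winding number (the end state of a
  ring-attractor network, whose neuron cloud is a circle).

* :func:`manifold_sample` draws noisy samples of reference manifolds with
  known topology (circle, flat torus, bounded sheet, sphere patch, Klein
  bottle, two planes glued at a point) used as oracles for the topology stack.

Everything is deterministic under the given seed.
"""

from __future__ import annotations

import numpy as np

from .config import N_PIXELS, PIXEL_SIZE

__all__ = [
    "grid_kernel",
    "hex_lattice_vectors",
    "ideal_grid_population",
    "ring_configured_population",
    "manifold_sample",
    "pixel_coordinates",
]


def hex_lattice_vectors(spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Primitive lattice vectors of a hexagonal lattice with nearest-neighbor
    distance `spacing` (first vector along +x)."""
    a1 = spacing * np.array([1.0, 0.0])
    a2 = spacing * np.array([0.5, np.sqrt(3) / 2])
    return a1, a2


def _wave_vectors(spacing: float, orientation: float = 0.0) -> np.ndarray:
    """Three wave vectors 120 degrees apart whose cosine sum peaks on a
    hexagonal lattice of the given spacing."""
    kmod = 4 * np.pi / (np.sqrt(3) * spacing)
    angles = orientation + np.deg2rad([90.0, 210.0, 330.0])
    return kmod * np.c_[np.cos(angles), np.sin(angles)]


def grid_kernel(xy: np.ndarray, spacing: float,
                orientation: float = 0.0) -> np.ndarray:
    """Ideal grid map f(x) = 1 + (2/3) sum_i cos(k_i . x).

    Ranges over [-1, 3]; its maxima (value 3) form a hexagonal lattice with
    nearest-neighbor distance `spacing`.
    """
    K = _wave_vectors(spacing, orientation)
    phases = xy @ K.T
    return 1.0 + (2.0 / 3.0) * np.cos(phases).sum(axis=-1)


def pixel_coordinates(n_px: int = N_PIXELS,
                      pixel_size: float = PIXEL_SIZE) -> np.ndarray:
    """(n_px, n_px, 2) array of pixel-center coordinates (cm), centered on the
    arena midpoint."""
    c = (np.arange(n_px) - (n_px - 1) / 2) * pixel_size
    gx, gy = np.meshgrid(c, c, indexing="ij")
    return np.stack([gx, gy], axis=-1)


def _phase_layout(kind: str, n_cells: int, spacing: float, winding: int,
                  rng: np.random.Generator, jitter: float) -> np.ndarray:
    a1, a2 = hex_lattice_vectors(spacing)
    if kind == "torus":
        side = int(round(np.sqrt(n_cells)))
        if side * side != n_cells:
            raise ValueError("torus phase layout needs a square cell count")
        u, v = np.meshgrid(np.arange(side) / side, np.arange(side) / side,
                           indexing="ij")
        uv = np.c_[u.ravel(), v.ravel()]
        uv = (uv + rng.uniform(-jitter, jitter, uv.shape)) % 1.0
        return np.outer(uv[:, 0], a1) + np.outer(uv[:, 1], a2)
    if kind == "random":
        uv = rng.uniform(0, 1, (n_cells, 2))
        return np.outer(uv[:, 0], a1) + np.outer(uv[:, 1], a2)
    if kind == "ring":
        s = np.arange(n_cells) / n_cells
        s = s + rng.uniform(-jitter, jitter, n_cells) / n_cells
        if winding == 0:
            # contractible cycle: a small loop inside one field
            r = 0.15 * spacing
            return r * np.c_[np.cos(2 * np.pi * s), np.sin(2 * np.pi * s)]
        return np.outer(s, winding * a1)
    if kind == "stripe":
        s = np.arange(n_cells) / max(n_cells - 1, 1)
        s = np.clip(s + rng.uniform(-jitter, jitter, n_cells) / n_cells, 0, 1)
        # span `winding` lattice vectors, roughly centered but anchored on
        # lattice points so the extremes sit on well-defined fields
        return np.outer(s * winding - round(winding / 2), a1)
    raise ValueError(f"unknown phase layout {kind!r}")


def ideal_grid_population(n_cells: int = 100, spacing: float = 60.0,
                          phase_layout: str = "torus", winding: int = 1,
                          noise_sd: float = 0.02, seed: int = 0,
                          orientation: float = 0.0,
                          jitter: float = 0.05,
                          envelope_sigma: float | None = None) -> np.ndarray:
    """Rate maps of an aligned grid population built from the ideal kernel.

    Parameters
    ----------
    n_cells : population size (square number for the torus layout).
    spacing : grid spacing in cm.
    phase_layout : 'torus' (phases uniform over the unit cell), 'random',
        'ring' (phases traversing a closed 1-cycle with the given winding
        number; winding=0 gives a contractible loop) or 'stripe' (open path).
    noise_sd : i.i.d. Gaussian noise s.d. as a fraction of the kernel peak.
    jitter : phase jitter as a fraction of the layout step, so that layouts
        are not perfectly degenerate lattices.
    envelope_sigma : optional Gaussian envelope s.d. (cm) multiplying each
        map around the cell's phase position.  Emulates the imperfect,
        spatially anchored tuning of trained stripe networks, whose two
        attractor extremes occupy distinct fields; without it, ideal maps
        are exactly lattice-periodic and the extremes coincide.

    Returns
    -------
    maps : (n_cells, 41, 41) nonnegative array; each map is the rectified
        kernel shifted by the cell's spatial phase, on the 2.4 cm pixel grid
        over the 1 m arena.
    """
    rng = np.random.default_rng(seed)
    phases = _phase_layout(phase_layout, n_cells, spacing, winding, rng, jitter)
    xy = pixel_coordinates()
    maps = np.empty((n_cells, xy.shape[0], xy.shape[1]))
    for c in range(n_cells):
        maps[c] = np.clip(grid_kernel(xy - phases[c], spacing, orientation),
                          0.0, None)
        if envelope_sigma is not None:
            d2 = ((xy - phases[c]) ** 2).sum(-1)
            maps[c] *= np.exp(-d2 / (2 * envelope_sigma ** 2))
    if noise_sd > 0:
        peak = 3.0
        maps += rng.normal(0.0, noise_sd * peak, maps.shape)
        np.clip(maps, 0.0, None, out=maps)
    return maps


def ring_configured_population(n_cells: int = 100, spacing: float = 60.0,
                               winding: int = 1, noise_sd: float = 0.02,
                               seed: int = 0) -> np.ndarray:
    """Population whose phases traverse `winding` cycles of the unit cell
    along one lattice direction (the O_n ring-attractor configurations)."""
    return ideal_grid_population(n_cells=n_cells, spacing=spacing,
                                 phase_layout="ring", winding=winding,
                                 noise_sd=noise_sd, seed=seed)


def manifold_sample(kind: str, n_points: int = 625, noise_sd: float = 0.01,
                    seed: int = 0, **kw) -> np.ndarray:
    """Noisy uniform sample of a reference manifold with known topology.

    kinds: 'circle' (R^2), 'torus' (flat torus, double-angle embedding in
    R^4), 'sheet' (bounded unit square in R^3), 'sphere_patch' (cap of S^2 in
    R^3, or of S^3 in R^4 with intrinsic_dim=3), 'klein' (Klein bottle
    embedded in R^4), 'two_planes' (two 2-planes in R^4 glued at the origin).
    Ambient Gaussian noise of s.d. `noise_sd` is added.
    """
    rng = np.random.default_rng(seed)
    if kind == "circle":
        th = 2 * np.pi * _stratified(rng, n_points)
        X = np.c_[np.cos(th), np.sin(th)]
    elif kind == "torus":
        m = int(round(np.sqrt(n_points)))
        if m * m == n_points:
            g = (np.arange(m) + 0.5) / m
            u, v = np.meshgrid(g, g, indexing="ij")
            u, v = u.ravel(), v.ravel()
            u = (u + rng.uniform(-0.2 / m, 0.2 / m, u.shape)) % 1
            v = (v + rng.uniform(-0.2 / m, 0.2 / m, v.shape)) % 1
        else:
            u = rng.uniform(0, 1, n_points)
            v = rng.uniform(0, 1, n_points)
        r = 1 / (2 * np.pi)
        X = np.c_[np.cos(2 * np.pi * u), np.sin(2 * np.pi * u),
                  np.cos(2 * np.pi * v), np.sin(2 * np.pi * v)] * r
    elif kind == "sheet":
        m = int(round(np.sqrt(n_points)))
        g = (np.arange(m) + 0.5) / m
        u, v = np.meshgrid(g, g, indexing="ij")
        u = u.ravel()[:n_points]
        v = v.ravel()[:n_points]
        X = np.c_[u, v, np.zeros_like(u)]
    elif kind == "sphere_patch":
        dim = int(kw.get("intrinsic_dim", 2))
        # cap of S^dim around the north pole, polar angle <= pi/3
        Z = rng.normal(size=(n_points, dim + 1))
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
        Z[:, -1] = np.abs(Z[:, -1])
        keep = Z[:, -1] >= np.cos(np.pi / 3)
        while keep.sum() < n_points:
            Z2 = rng.normal(size=(n_points, dim + 1))
            Z2 /= np.linalg.norm(Z2, axis=1, keepdims=True)
            Z2[:, -1] = np.abs(Z2[:, -1])
            Z = np.vstack([Z[keep], Z2[Z2[:, -1] >= np.cos(np.pi / 3)]])
            keep = np.ones(len(Z), bool)
        X = Z[:n_points]
    elif kind == "klein":
        u = rng.uniform(0, 2 * np.pi, n_points)
        v = rng.uniform(0, 2 * np.pi, n_points)
        a, r = 1.0, 0.4
        X = np.c_[(a + r * np.cos(v)) * np.cos(u),
                  (a + r * np.cos(v)) * np.sin(u),
                  r * np.sin(v) * np.cos(u / 2),
                  r * np.sin(v) * np.sin(u / 2)]
    elif kind == "two_planes":
        # two orthogonal 2-planes in R^4 intersecting only at the origin
        half = n_points // 2
        A = rng.uniform(-1, 1, (half, 2))
        B = rng.uniform(-1, 1, (n_points - half, 2))
        X = np.zeros((n_points, 4))
        X[:half, :2] = A
        X[half:, 2:] = B
    else:
        raise ValueError(f"unknown manifold kind {kind!r}")
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, X.shape)
    return X


def _stratified(rng: np.random.Generator, n: int) -> np.ndarray:
    """Stratified uniform sample of [0, 1) (reduces clumping at small n)."""
    return (np.arange(n) + rng.uniform(0, 1, n)) / n
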