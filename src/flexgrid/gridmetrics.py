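"""Hexagonality metrics of rate maps: autocorrelograms, spacing, gridness,
and population alignment (angular spread of autocorrelogram maxima).

The spatial autocorrelogram of a map is the Pearson correlation of the map
with itself at every integer-pixel displacement (computed over the
overlapping region).  A circular Hamming taper of 1 m radius centered on zero
lag suppresses the noisy large-lag corners where the overlap is small; the
taper is used for peak/maxima detection and the spacing search, while
gridness reads the untapered correlation values, whose scale is
interpretable (-1..1).

Spacing is the radius at which the angular profile of the autocorrelogram
has maximal 6-fold Fourier modulation; gridness is the mean correlation at
the six 60-degree-spaced maxima at that radius minus the mean at the six
interleaved minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, maximum_filter
from scipy.signal import fftconvolve
from sklearn.cluster import KMeans

from .config import PIXEL_SIZE

__all__ = [
    "Autocorrelogram", "GridScores",
    "compute_autocorrelogram", "population_autocorrelogram",
    "estimate_spacing", "compute_gridness", "detect_maxima",
    "compute_angular_spread", "grid_scores",
]

WINDOW_RADIUS = 100.0   # cm; Hamming taper support
MIN_OVERLAP = 20        # pixels; displacements with less overlap are zeroed
SPACING_MIN_RADIUS = 2  # pixels; excludes the central peak
RING_POWER_FLOOR = 0.1  # min mean |correlation| on the winning ring; noise
                        # maps stay below ~0.07, hexagonal maps reach ~0.45


@dataclass
class Autocorrelogram:
    """Windowed and raw Pearson spatial autocorrelation at all displacements.

    `values` carries the Hamming-tapered correlogram (used for detection),
    `raw` the plain correlation values; both are (2 n_px - 1) squares with
    zero lag at the center."""

    values: np.ndarray
    raw: np.ndarray
    lag_step: float = PIXEL_SIZE
    window_applied: bool = True

    @property
    def center(self) -> int:
        return self.values.shape[0] // 2


@dataclass
class GridScores:
    gridness: float
    spacing: float               # cm
    maxima: np.ndarray           # (m, 2) lag coordinates in cm
    flagged: bool = False        # no reliable 6-fold modulation


def _pearson_autocorr(m: np.ndarray) -> np.ndarray:
    """Pearson correlation of a map with itself at all displacements."""
    m = np.asarray(m, dtype=float)
    ones = np.ones_like(m)
    flip = m[::-1, ::-1]
    n = fftconvolve(ones, ones[::-1, ::-1])
    s1 = fftconvolve(m, ones[::-1, ::-1])
    s2 = fftconvolve(ones, flip)
    s11 = fftconvolve(m * m, ones[::-1, ::-1])
    s22 = fftconvolve(ones, flip * m[::-1, ::-1])
    s12 = fftconvolve(m, flip)
    n = np.round(n)
    cov = n * s12 - s1 * s2
    v1 = n * s11 - s1 ** 2
    v2 = n * s22 - s2 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(np.clip(v1, 0, None) * np.clip(v2, 0, None))
    r[~np.isfinite(r)] = 0.0
    r[n < MIN_OVERLAP] = 0.0
    return np.clip(r, -1.0, 1.0)


def _hamming_taper(shape: int, lag_step: float) -> np.ndarray:
    c = shape // 2
    yy, xx = np.mgrid[0:shape, 0:shape]
    r = np.hypot(xx - c, yy - c) * lag_step
    w = 0.54 + 0.46 * np.cos(np.pi * np.clip(r / WINDOW_RADIUS, 0, 1))
    w[r > WINDOW_RADIUS] = 0.0
    return w


def compute_autocorrelogram(m: np.ndarray) -> Autocorrelogram:
    """Windowed spatial autocorrelogram of one rate map.

    A constant map has undefined correlation; it yields an all-zero
    correlogram (which downstream scoring flags)."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("rate map must be 2D")
    if np.ptp(m) < 1e-12:
        raw = np.zeros((2 * m.shape[0] - 1,) * 2)
        return Autocorrelogram(raw.copy(), raw)
    raw = _pearson_autocorr(m)
    w = _hamming_taper(raw.shape[0], PIXEL_SIZE)
    return Autocorrelogram(raw * w, raw)


def population_autocorrelogram(maps: np.ndarray) -> Autocorrelogram:
    """Elementwise mean of the per-cell autocorrelograms."""
    acs = [compute_autocorrelogram(m) for m in maps]
    return Autocorrelogram(np.mean([a.values for a in acs], axis=0),
                           np.mean([a.raw for a in acs], axis=0))


def _polar_profile(values: np.ndarray, radii_px: np.ndarray,
                   n_angles: int = 360) -> np.ndarray:
    """Bilinear interpolation of the correlogram onto a polar grid
    (radius x angle)."""
    c = values.shape[0] // 2
    th = np.deg2rad(np.arange(n_angles))
    rr, tt = np.meshgrid(radii_px, th, indexing="ij")
    xs = c + rr * np.cos(tt)
    ys = c + rr * np.sin(tt)
    return map_coordinates(values, [xs.ravel(), ys.ravel()], order=1,
                           mode="constant").reshape(len(radii_px), n_angles)


def estimate_spacing(ac: Autocorrelogram) -> tuple[float, bool]:
    """Grid spacing from the 6-fold angular Fourier modulation.

    Interpolates the correlogram to polar coordinates (1-pixel radius step,
    1-degree angle step) and returns the radius (cm) with maximal magnitude
    of the 6th angular Fourier coefficient, searched from 2 pixels to the
    lag-grid edge.  The search runs on the untapered correlation (the taper
    falls off with radius and biases the argmax inward by one bin); the taper
    already bounds the search region.  Returns (spacing_cm, flagged);
    flagged when the winning ring carries almost no correlation mass, as for
    noise maps without any hexagonal ring.
    """
    c = ac.center
    radii = np.arange(SPACING_MIN_RADIUS, c + 1)
    prof = _polar_profile(ac.raw, radii)
    coef6 = np.abs((prof * np.exp(-6j * np.deg2rad(np.arange(360)))).mean(1))
    best = int(np.argmax(coef6))
    spacing = float(radii[best] * ac.lag_step)
    power = np.abs(prof[best]).mean()
    return spacing, bool(power < RING_POWER_FLOOR)


def compute_gridness(ac: Autocorrelogram,
                     spacing: float | None = None) -> float:
    """Mean raw correlation at the six 60-degree-spaced maxima of the spacing
    ring minus the mean at the six interleaved (30-degree offset) minima."""
    if spacing is None:
        spacing, _ = estimate_spacing(ac)
    r_px = spacing / ac.lag_step
    prof = _polar_profile(ac.raw, np.array([r_px]))[0]
    th = np.deg2rad(np.arange(360))
    c6 = (prof * np.exp(-6j * th)).mean()
    phase = np.angle(c6)  # modulation ~ cos(6 theta + phase)
    peak0 = (-np.rad2deg(phase) / 6.0) % 60.0
    peaks = (peak0 + 60.0 * np.arange(6)) % 360
    troughs = (peaks + 30.0) % 360
    pk = np.interp(peaks, np.arange(360), prof, period=360)
    tr = np.interp(troughs, np.arange(360), prof, period=360)
    return float(pk.mean() - tr.mean())


def detect_maxima(ac: Autocorrelogram, spacing: float | None = None,
                  n_keep: int = 6) -> np.ndarray:
    """First-order maxima of the windowed correlogram: local maxima inside
    the annulus [0.5, 1.5] x spacing, the `n_keep` largest by value.
    Returns (m, 2) lag coordinates in cm (may hold fewer than n_keep)."""
    if spacing is None:
        spacing, _ = estimate_spacing(ac)
    v = ac.values
    c = ac.center
    loc = (maximum_filter(v, size=3, mode="constant") == v)
    yy, xx = np.mgrid[0:v.shape[0], 0:v.shape[1]]
    r = np.hypot(xx - c, yy - c) * ac.lag_step
    mask = loc & (r >= 0.5 * spacing) & (r <= 1.5 * spacing)
    i0, i1 = np.nonzero(mask)
    if len(i0) == 0:
        return np.empty((0, 2))
    order = np.argsort(v[i0, i1])[::-1][:n_keep]
    return np.c_[(i0[order] - c), (i1[order] - c)] * ac.lag_step


def grid_scores(m: np.ndarray) -> GridScores:
    """Full scoring of one rate map."""
    ac = compute_autocorrelogram(m)
    spacing, flagged = estimate_spacing(ac)
    g = compute_gridness(ac, spacing)
    maxima = detect_maxima(ac, spacing)
    return GridScores(g, spacing, maxima, flagged)


def compute_angular_spread(maps: np.ndarray, n_clusters: int = 6,
                           random_state: int = 0) -> float:
    """Alignment of the population: pool the first-order autocorrelogram
    maxima of every map, cluster them into `n_clusters` groups (k-means, 10
    restarts), and return the mean absolute pairwise angle difference (deg)
    within clusters.  Maps with fewer than 6 detected maxima are skipped;
    needs at least 2 usable maps."""
    pool = []
    used = 0
    for m in maps:
        ac = compute_autocorrelogram(m)
        spacing, flagged = estimate_spacing(ac)
        if flagged:
            continue  # no hexagonal ring: maxima are meaningless
        mx = detect_maxima(ac, spacing)
        if len(mx) < 6:
            continue
        pool.append(mx)
        used += 1
    if used < 2:
        raise ValueError("need at least 2 maps with 6 detected maxima")
    pts = np.concatenate(pool)
    km = KMeans(n_clusters=n_clusters, n_init=10,
                random_state=random_state).fit(pts)
    ang = np.rad2deg(np.arctan2(pts[:, 1], pts[:, 0])) % 360
    diffs = []
    for cl in range(n_clusters):
        a = ang[km.labels_ == cl]
        if len(a) < 2:
            continue
        d = np.abs(a[:, None] - a[None])
        d = np.minimum(d, 360 - d)
        iu = np.triu_indices(len(a), k=1)
        diffs.append(d[iu])
    if not diffs:
        return 0.0
    return float(np.concatenate(diffs).mean())
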