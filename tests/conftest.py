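import itertools

import numpy as np
import pytest

from flexgrid.config import CROP_SLICE
from flexgrid.fixtures import ideal_grid_population, manifold_sample


def brute_force_betti(D, t, p, max_dim=2):
    """Betti numbers of the Rips complex at scale t, by GF(p) rank
    computation on explicit boundary matrices (oracle for small clouds)."""
    n = D.shape[0]
    simplices = {0: [(i,) for i in range(n)]}
    for d in range(1, max_dim + 2):
        simplices[d] = [
            s for s in itertools.combinations(range(n), d + 1)
            if max(D[a, b] for a, b in itertools.combinations(s, 2)) <= t]
    index = {d: {s: i for i, s in enumerate(simplices[d])} for d in simplices}

    def boundary(d):
        M = np.zeros((len(simplices[d - 1]), len(simplices[d])),
                     dtype=np.int64)
        for j, s in enumerate(simplices[d]):
            for q in range(d + 1):
                M[index[d - 1][s[:q] + s[q + 1:]], j] = (-1) ** q % p
        return M

    def rank_gf(M):
        M = M.copy() % p
        r = 0
        rows, cols = M.shape
        for c in range(cols):
            piv = next((rr for rr in range(r, rows) if M[rr, c] % p), None)
            if piv is None:
                continue
            M[[r, piv]] = M[[piv, r]]
            M[r] = (M[r] * pow(int(M[r, c]), p - 2, p)) % p
            for rr in range(rows):
                if rr != r and M[rr, c]:
                    M[rr] = (M[rr] - M[rr, c] * M[r]) % p
            r += 1
            if r == rows:
                break
        return r

    betti = []
    for d in range(max_dim + 1):
        nd = len(simplices[d])
        rk_d = rank_gf(boundary(d)) if d > 0 and nd else 0
        rk_up = rank_gf(boundary(d + 1)) if len(simplices[d + 1]) else 0
        betti.append(nd - rk_d - rk_up)
    return tuple(betti)


def betti_at_scale(summary, t):
    """Betti numbers of one summary at a fixed Rips scale (the bar counting
    convention: born at or before t, dead strictly after t; the longest H0
    bar is the essential component)."""
    out = []
    for d in sorted(summary.diagrams):
        dg = summary.diagrams[d]
        if len(dg) == 0:
            out.append(0)
            continue
        birth = dg[:, 0]
        death = dg[:, 0] + dg[:, 1]
        if d == 0:
            death = death.copy()
            death[np.argmax(dg[:, 1])] = np.inf
        out.append(int(np.sum((birth <= t) & (death > t))))
    return tuple(out)


@pytest.fixture(scope="session")
def torus_population_maps():
    """Aligned 100-cell grid population with phases uniform on the unit cell
    (the 2D-attractor end state); 2% noise."""
    return ideal_grid_population(100, 60.0, "torus", noise_sd=0.02, seed=1)


@pytest.fixture(scope="session")
def torus_population_cloud(torus_population_maps):
    m = torus_population_maps[:, CROP_SLICE, CROP_SLICE]
    return m.reshape(100, -1).T  # 625 points in R^100


@pytest.fixture(scope="session")
def torus_sample_625():
    return manifold_sample("torus", 625, noise_sd=0.01, seed=1)
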