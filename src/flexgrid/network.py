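"""Self-organizing grid-cell network with configurable recurrent collaterals.

A virtual rat random-walks a 1 m square arena.  225 place-cell-like inputs
with Gaussian fields feed a layer of 100 grid cells through a Hebbian
feedforward matrix; the grid layer carries firing-rate adaptation, global
inhibition implemented as a rank threshold (only the top `active_fraction` of
cells fire, normalized so the population mean rate equals the gain G), and a
fixed matrix of excitatory recurrent collaterals whose architecture is
pluggable: a 2D torus, a 1D ring, a 1D stripe, an overlap of short random
stripe fragments, or none.  Hebbian learning sculpts hexagonal firing maps;
the recurrent collaterals align their axes across the population.

Per-step update order: position -> input rates -> total field (feedforward +
recurrent, the latter using the previous step's grid rates) -> adaptation ->
threshold-linear transfer -> Hebbian update -> rate-map accumulation.

`run_simulation` executes the whole loop in a single numba kernel; the
individual operations are also exposed as plain-numpy functions and the
kernel is tested against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from numba import njit

from .config import (ARENA_SIDE, N_PIXELS, PIXEL_SIZE, SimulationConfig)

__all__ = [
    "NetworkState", "RateMapStack", "Trajectory",
    "generate_trajectory", "input_centers", "input_rates",
    "compute_fields", "adaptation_step", "apply_transfer", "hebbian_update",
    "update_rate_maps",
    "build_torus_architecture", "build_ring_architecture",
    "build_stripe_architecture", "build_fragmented_architecture",
    "build_recurrent", "run_simulation",
]

_RIN_FLOOR = 1e-6    # input rates below this are treated as silent
_RBAR_FLOOR = 1e-10  # running averages below this are snapped to zero
_DENOM_GUARD = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    positions: np.ndarray  # (n_steps, 2) cm
    headings: np.ndarray   # (n_steps,) radians


@dataclass
class NetworkState:
    """Weights and dynamical variables of the simulated network."""

    W_in: np.ndarray       # (n_grid, n_input), rows in the unit ball, >= 0
    W_rec: np.ndarray      # (n_grid, n_grid), row-L1-normalized, >= 0, fixed
    h_act: np.ndarray
    h_inact: np.ndarray
    r_grid: np.ndarray
    r_bar_grid: np.ndarray
    r_bar_in: np.ndarray

    @classmethod
    def initial(cls, config: SimulationConfig,
                rng: np.random.Generator) -> "NetworkState":
        """Uniform(0,1) feedforward rows scaled to unit norm; zero internal
        variables; recurrent matrix per the configured architecture."""
        W = rng.uniform(0.0, 1.0, (config.n_grid, config.n_input))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        W_rec = build_recurrent(config, rng)
        z = np.zeros(config.n_grid)
        return cls(W, W_rec, z.copy(), z.copy(), z.copy(), z.copy(),
                   np.zeros(config.n_input))


@dataclass
class RateMapStack:
    """Per-neuron mean-rate maps on the fixed 2.4 cm pixel grid."""

    maps: np.ndarray                  # (n_grid, 41, 41), >= 0
    pixel_size: float = PIXEL_SIZE
    occupancy: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.maps.shape[0]


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gen_trajectory(n_steps, step, turn_sd, arena, x0, y0, h0, seed):
    np.random.seed(seed)
    pos = np.empty((n_steps, 2))
    heads = np.empty(n_steps)
    x, y, h = x0, y0, h0
    for t in range(n_steps):
        for _ in range(10000):
            turn = np.random.normal(0.0, turn_sd)
            nh = h + turn
            nx = x + step * np.cos(nh)
            ny = y + step * np.sin(nh)
            if 0.0 <= nx <= arena and 0.0 <= ny <= arena:
                break
        else:
            nh = np.arctan2(arena / 2 - y, arena / 2 - x)
            nx = x + step * np.cos(nh)
            ny = y + step * np.sin(nh)
        x, y, h = nx, ny, nh
        pos[t, 0] = x
        pos[t, 1] = y
        heads[t] = h
    return pos, heads


def generate_trajectory(config: SimulationConfig,
                        seed: int | None = None) -> Trajectory:
    """Random walk of `n_steps` fixed-length steps inside the arena.

    Heading increments are i.i.d. normal with s.d. `turn_sd` degrees; a step
    that would leave the arena redraws its turn until it stays inside.  Starts
    at the arena center with a heading drawn from the seed.
    """
    if config.n_steps <= 0:
        raise ValueError("n_steps must be positive")
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    sub = int(ss.generate_state(1)[0] % (2 ** 31))
    h0 = float(np.random.default_rng(seed).uniform(0, 2 * np.pi))
    pos, heads = _gen_trajectory(
        config.n_steps, config.step_length, np.deg2rad(config.turn_sd),
        config.arena_side, config.arena_side / 2, config.arena_side / 2,
        h0, sub)
    return Trajectory(pos, heads)


# ---------------------------------------------------------------------------
# input layer
# ---------------------------------------------------------------------------

def input_centers(config: SimulationConfig) -> np.ndarray:
    """Preferred positions of the input cells: a uniform sqrt(n) x sqrt(n)
    lattice over the arena (cell centers)."""
    side = int(round(np.sqrt(config.n_input)))
    if side * side != config.n_input:
        raise ValueError("n_input must be a perfect square")
    c = (np.arange(side) + 0.5) * config.arena_side / side
    gx, gy = np.meshgrid(c, c, indexing="ij")
    return np.c_[gx.ravel(), gy.ravel()]


def input_rates(position, config: SimulationConfig,
                centers: np.ndarray | None = None) -> np.ndarray:
    """Gaussian place-field rates r_j = peak * exp(-d_j^2 / (2 sigma^2))."""
    if centers is None:
        centers = input_centers(config)
    d2 = ((centers - np.asarray(position)) ** 2).sum(axis=1)
    return config.input_peak_rate * np.exp(-d2 / (2 * config.input_sigma ** 2))


# ---------------------------------------------------------------------------
# single-step dynamics (reference implementations)
# ---------------------------------------------------------------------------

def compute_fields(state: NetworkState, r_in: np.ndarray,
                   config: SimulationConfig) -> np.ndarray:
    """Total field h = W_in r_in + recurrent drive.

    The recurrent drive uses the grid rates of the previous step: row-L1-
    normalized collateral weights times the rates, scaled by the recurrent
    gain and divided by the mean grid rate, so that both contributions stay
    of the same order of magnitude throughout learning."""
    if r_in.shape[0] != state.W_in.shape[1]:
        raise ValueError("input rate vector has the wrong size")
    h = state.W_in @ r_in
    mean_r = float(np.mean(state.r_grid))
    if mean_r > _DENOM_GUARD and config.recurrent_gain != 0:
        h = h + (config.recurrent_scale * config.recurrent_gain / mean_r) * \
            (state.W_rec @ state.r_grid)
    return h


def adaptation_step(h: np.ndarray, h_inact: np.ndarray,
                    beta: float) -> tuple[np.ndarray, np.ndarray]:
    """Neural fatigue: h_act(t+1) = h(t) - h_inact(t), and the inactivation
    variable integrates it, h_inact(t+1) = h_inact(t) + beta * h_act(t+1).
    Under constant drive h_inact converges to h and h_act to zero."""
    h_act = h - h_inact
    return h_act, h_inact + beta * h_act


def apply_transfer(h_act: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Threshold-linear transfer with rank inhibition.

    The threshold T is the highest activation among the excluded cells, so
    that exactly ceil(active_fraction * n_grid) cells are positive (ties
    broken by index order); rates are G * (h_act - T)_+ normalized by the
    mean rectified value over all cells, making the population mean rate
    exactly G."""
    n = h_act.shape[0]
    k = int(np.ceil(config.active_fraction * n))
    r = np.zeros(n)
    if k == 0:
        return r
    order = np.argsort(h_act, kind="stable")
    sel = order[n - k:]
    if k < n:
        T = h_act[order[n - k - 1]]
    else:
        T = 0.0
    vals = np.clip(h_act[sel] - T, 0.0, None)
    denom = vals.sum() / n
    if denom < _DENOM_GUARD:
        return r
    r[sel] = config.gain_G * vals / denom
    return r


def hebbian_update(state: NetworkState, r_in: np.ndarray, r_grid: np.ndarray,
                   config: SimulationConfig) -> None:
    """In-place Hebbian update of the feedforward weights.

    dW_ij = eps * (r^I_j r^EC_i - rbar^I_j rbar^EC_i); negative weights are
    clipped to zero and any row with Euclidean norm above 1 is rescaled onto
    the unit sphere.  Afterwards the running averages are updated as
    rbar <- rbar (1 - delta) + r delta."""
    W = state.W_in
    W += config.epsilon_learn * (
        np.outer(r_grid, r_in) - np.outer(state.r_bar_grid, state.r_bar_in))
    np.clip(W, 0.0, None, out=W)
    norms = np.linalg.norm(W, axis=1)
    over = norms > 1.0
    W[over] /= norms[over, None]
    d = config.delta_avg
    state.r_bar_in = state.r_bar_in * (1 - d) + r_in * d
    state.r_bar_grid = state.r_bar_grid * (1 - d) + r_grid * d


def update_rate_maps(maps: np.ndarray, position, r_grid: np.ndarray,
                     config: SimulationConfig) -> None:
    """Exponential mean-rate update of the single occupied pixel:
    m_j <- m_j (1 - tau) + r_j tau."""
    n_px = maps.shape[1]
    px, py = _pixel_of(position[0], position[1], config.arena_side, n_px)
    maps[:, px, py] = maps[:, px, py] * (1 - config.tau_map) + \
        r_grid * config.tau_map


@njit(cache=True, inline="always")
def _pixel_of(x, y, arena, n_px):
    half = arena / 2.0
    px = int((x - half) / PIXEL_SIZE + n_px / 2.0)
    py = int((y - half) / PIXEL_SIZE + n_px / 2.0)
    if px < 0:
        px = 0
    if px >= n_px:
        px = n_px - 1
    if py < 0:
        py = 0
    if py >= n_px:
        py = n_px - 1
    return px, py


# ---------------------------------------------------------------------------
# recurrent collateral architectures
# ---------------------------------------------------------------------------

def _row_l1_normalize(W: np.ndarray) -> np.ndarray:
    s = W.sum(axis=1, keepdims=True)
    s[s < _DENOM_GUARD] = 1.0
    return W / s


def build_torus_architecture(config: SimulationConfig) -> np.ndarray:
    """2D attractor: neurons on a periodic square lattice over the arena,
    connected by the rectified three-cosine grid kernel of their relative
    (minimum-image) position, with the kernel spacing set by
    `kernel_spacing` (60 cm)."""
    from .fixtures import grid_kernel
    n = config.n_grid
    side = int(round(np.sqrt(n)))
    if side * side != n:
        raise ValueError("torus architecture needs a square n_grid")
    L = config.arena_side
    c = np.arange(side) * L / side
    gx, gy = np.meshgrid(c, c, indexing="ij")
    pos = np.c_[gx.ravel(), gy.ravel()]
    diff = pos[:, None] - pos[None]
    diff = (diff + L / 2) % L - L / 2  # minimum-image wrap (torus)
    W = grid_kernel(diff, config.kernel_spacing)
    np.clip(W, 0.0, None, out=W)     # excitatory collaterals only
    np.fill_diagonal(W, 0.0)
    return W


def build_ring_architecture(config: SimulationConfig) -> np.ndarray:
    """1D ring attractor: neurons spaced by `ring_spacing_deg` on a circle,
    Gaussian connectivity in the minimum angular distance."""
    n = config.n_grid
    ang = np.deg2rad(config.ring_spacing_deg) * np.arange(n)
    d = np.abs(ang[:, None] - ang[None])
    d = np.minimum(d, 2 * np.pi - d)
    sig = np.deg2rad(config.ring_sigma_deg)
    W = np.exp(-d ** 2 / (2 * sig ** 2))
    np.fill_diagonal(W, 0.0)
    return W


def build_stripe_architecture(config: SimulationConfig,
                              n_cells: int | None = None) -> np.ndarray:
    """1D stripe (linear) attractor: neurons on a line with unit spacing,
    Gaussian connectivity of s.d. twice the inter-neuron distance, no
    wrap-around."""
    n = config.n_grid if n_cells is None else n_cells
    pos = np.arange(n, dtype=float)
    d = np.abs(pos[:, None] - pos[None])
    W = np.exp(-d ** 2 / (2 * 2.0 ** 2))
    np.fill_diagonal(W, 0.0)
    return W


def build_fragmented_architecture(config: SimulationConfig,
                                  rng: np.random.Generator) -> np.ndarray:
    """Overlap of `fragment_repeats` short stripe attractors, each connecting
    `fragment_size` randomly chosen cells in draw order."""
    n = config.n_grid
    W = np.zeros((n, n))
    frag = build_stripe_architecture(config, n_cells=config.fragment_size)
    for _ in range(config.fragment_repeats):
        cells = rng.choice(n, size=config.fragment_size, replace=False)
        W[np.ix_(cells, cells)] += frag
    np.fill_diagonal(W, 0.0)
    return W


def build_recurrent(config: SimulationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Dispatch on the configured architecture; returns the row-L1-normalized
    nonnegative collateral matrix (zero for 'none'), optionally with each
    row's presynaptic identities shuffled (control condition)."""
    arch = config.architecture
    if arch == "none":
        return np.zeros((config.n_grid, config.n_grid))
    if arch == "torus2d":
        W = build_torus_architecture(config)
    elif arch == "ring1d":
        W = build_ring_architecture(config)
    elif arch == "stripe1dl":
        W = build_stripe_architecture(config)
    elif arch == "fragmented":
        W = build_fragmented_architecture(config, rng)
    else:  # pragma: no cover - guarded by SimulationConfig
        raise ValueError(arch)
    if config.shuffle_recurrent:
        for i in range(W.shape[0]):
            off = np.delete(np.arange(W.shape[0]), i)
            W[i, off] = W[i, rng.permutation(off)]
    return _row_l1_normalize(W)


# ---------------------------------------------------------------------------
# fused simulation kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_core(n_steps, seed, step_len, turn_sd, arena,
              centers, peak, sigma2,
              WinT, Wrec_T, use_rec, rec_gain_scale,
              beta, G, k_active, eps, delta, tau,
              n_px, maps, checkpoint_every, ckpt_maps, ckpt_steps,
              attractor_off_step, traj, use_traj):
    """Full simulation loop.  WinT is the transposed feedforward matrix
    (n_input, n_grid) and is modified in place together with `maps`."""
    np.random.seed(seed)
    n_in = WinT.shape[0]
    n_g = WinT.shape[1]

    # lazy per-row scale: effective W = s_i * WinT[:, i]
    s = np.ones(n_g)
    rawsq = np.zeros(n_g)
    for i in range(n_g):
        acc = 0.0
        for j in range(n_in):
            acc += WinT[j, i] * WinT[j, i]
        rawsq[i] = acc

    h_inact = np.zeros(n_g)
    r_grid = np.zeros(n_g)
    rbar_g = np.zeros(n_g)
    rbar_in = np.zeros(n_in)
    r_in = np.zeros(n_in)
    h = np.empty(n_g)
    h_act = np.empty(n_g)
    vals = np.empty(n_g)

    x = arena / 2.0
    y = arena / 2.0
    head = np.random.uniform(0.0, 2.0 * np.pi)
    n_ckpt = 0

    for t in range(n_steps):
        if use_traj:
            x = traj[t, 0]
            y = traj[t, 1]
        else:
            # trajectory step (redraw turns that would exit the arena)
            ok = False
            for _ in range(10000):
                nh = head + np.random.normal(0.0, turn_sd)
                nx = x + step_len * np.cos(nh)
                ny = y + step_len * np.sin(nh)
                if 0.0 <= nx <= arena and 0.0 <= ny <= arena:
                    ok = True
                    break
            if not ok:
                nh = np.arctan2(arena / 2 - y, arena / 2 - x)
                nx = x + step_len * np.cos(nh)
                ny = y + step_len * np.sin(nh)
            x, y, head = nx, ny, nh

        # --- input rates (sparse support)
        for j in range(n_in):
            dx = centers[j, 0] - x
            dy = centers[j, 1] - y
            r = peak * np.exp(-(dx * dx + dy * dy) / (2.0 * sigma2))
            r_in[j] = r if r > _RIN_FLOOR else 0.0

        # --- total field
        rec_on = use_rec and (attractor_off_step < 0 or t < attractor_off_step)
        mean_r = 0.0
        for i in range(n_g):
            mean_r += r_grid[i]
        mean_r /= n_g
        for i in range(n_g):
            h[i] = 0.0
        for j in range(n_in):
            rj = r_in[j]
            if rj > 0.0:
                for i in range(n_g):
                    h[i] += WinT[j, i] * rj
        for i in range(n_g):
            h[i] *= s[i]
        if rec_on and mean_r > _DENOM_GUARD:
            c = rec_gain_scale / mean_r
            for k in range(n_g):
                rk = r_grid[k]
                if rk > 0.0:
                    crk = c * rk
                    for i in range(n_g):
                        h[i] += Wrec_T[k, i] * crk

        # --- adaptation
        for i in range(n_g):
            h_act[i] = h[i] - h_inact[i]
            h_inact[i] += beta * h_act[i]

        # --- threshold-linear transfer with rank inhibition
        for i in range(n_g):
            vals[i] = h_act[i]
        vals_sorted = np.sort(vals)
        T = vals_sorted[n_g - k_active - 1] if k_active < n_g else 0.0
        acc = 0.0
        for i in range(n_g):
            v = h_act[i] - T
            if v > 0.0:
                acc += v
        denom = acc / n_g
        if denom < _DENOM_GUARD:
            for i in range(n_g):
                r_grid[i] = 0.0
        else:
            for i in range(n_g):
                v = h_act[i] - T
                r_grid[i] = G * v / denom if v > 0.0 else 0.0

        # --- Hebbian update on the active input support
        for j in range(n_in):
            if r_in[j] > 0.0 or rbar_in[j] > _RBAR_FLOOR:
                rj = r_in[j]
                bj = rbar_in[j]
                for i in range(n_g):
                    d_eff = eps * (rj * r_grid[i] - bj * rbar_g[i])
                    if d_eff != 0.0:
                        old = WinT[j, i]
                        new = old + d_eff / s[i]
                        if new < 0.0:
                            new = 0.0
                        WinT[j, i] = new
                        rawsq[i] += new * new - old * old
        for i in range(n_g):
            if rawsq[i] < 0.0:
                rawsq[i] = 0.0
            nrm2 = s[i] * s[i] * rawsq[i]
            if nrm2 > 1.0:
                s[i] /= np.sqrt(nrm2)
            if s[i] < 1e-6:  # refold the lazy scale into the raw weights
                for j in range(n_in):
                    WinT[j, i] *= s[i]
                rawsq[i] *= s[i] * s[i]
                s[i] = 1.0

        # --- running averages
        for i in range(n_g):
            rbar_g[i] = rbar_g[i] * (1.0 - delta) + r_grid[i] * delta
        for j in range(n_in):
            b = rbar_in[j] * (1.0 - delta) + r_in[j] * delta
            rbar_in[j] = b if b > _RBAR_FLOOR else 0.0

        # --- rate map accumulation (occupied pixel only)
        px, py = _pixel_of(x, y, arena, n_px)
        for i in range(n_g):
            maps[i, px, py] = maps[i, px, py] * (1.0 - tau) + r_grid[i] * tau

        # --- checkpoints
        if checkpoint_every > 0 and (t + 1) % checkpoint_every == 0 \
                and n_ckpt < ckpt_maps.shape[0]:
            ckpt_maps[n_ckpt] = maps
            ckpt_steps[n_ckpt] = t + 1
            n_ckpt += 1

    # fold scales back into the weights
    for i in range(n_g):
        for j in range(n_in):
            WinT[j, i] *= s[i]
    return h_inact, r_grid, rbar_g, rbar_in, n_ckpt


def run_simulation(config: SimulationConfig, checkpoint_every: float = 0.05,
                   trajectory: Trajectory | None = None):
    """Run the full self-organization loop.

    Returns (state, RateMapStack, checkpoints) where checkpoints is a list of
    (step, maps snapshot) taken every `checkpoint_every` fraction of the run.
    A precomputed `trajectory` may be supplied (otherwise one is generated
    from the config seed).  Raises if any state variable goes non-finite.
    """
    rng = np.random.default_rng(config.seed)
    state = NetworkState.initial(config, rng)
    centers = input_centers(config)
    ss = np.random.SeedSequence(config.seed)
    kernel_seed = int(ss.generate_state(1)[0] % (2 ** 31))

    n_ckpt = int(round(1.0 / checkpoint_every)) if checkpoint_every > 0 else 0
    every = int(config.n_steps * checkpoint_every) if n_ckpt else 0
    n_px = N_PIXELS
    maps = np.zeros((config.n_grid, n_px, n_px))
    ckpt_maps = np.zeros((n_ckpt, config.n_grid, n_px, n_px))
    ckpt_steps = np.zeros(n_ckpt, dtype=np.int64)

    off_step = -1
    if config.attractor_off_fraction is not None:
        off_step = int(config.attractor_off_fraction * config.n_steps)

    WinT = np.ascontiguousarray(state.W_in.T)
    Wrec_T = np.ascontiguousarray(state.W_rec.T)
    use_rec = config.architecture != "none" and config.recurrent_gain != 0

    if trajectory is not None:
        traj = np.ascontiguousarray(trajectory.positions[:config.n_steps])
        use_traj = True
    else:
        traj = np.zeros((1, 2))
        use_traj = False

    h_inact, r_grid, rbar_g, rbar_in, got = _run_core(
        config.n_steps, kernel_seed, config.step_length,
        np.deg2rad(config.turn_sd), config.arena_side,
        centers, config.input_peak_rate, config.input_sigma ** 2,
        WinT, Wrec_T, use_rec,
        config.recurrent_scale * config.recurrent_gain,
        config.beta_adapt, config.gain_G, config.n_active,
        config.epsilon_learn, config.delta_avg, config.tau_map,
        n_px, maps, every, ckpt_maps, ckpt_steps, off_step, traj, use_traj)

    for name, arr in (("W_in", WinT), ("maps", maps), ("h_inact", h_inact),
                      ("r_grid", r_grid)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                f"non-finite values in {name} after {config.n_steps} steps "
                f"(architecture={config.architecture})")

    state.W_in = np.ascontiguousarray(WinT.T)
    state.h_inact = h_inact
    state.h_act = np.zeros_like(h_inact)
    state.r_grid = r_grid
    state.r_bar_grid = rbar_g
    state.r_bar_in = rbar_in
    checkpoints = [(int(ckpt_steps[i]), ckpt_maps[i]) for i in range(got)]
    return state, RateMapStack(maps), checkpoints
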