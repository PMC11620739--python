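"""Simulation configuration and shared spatial constants.

Defaults reproduce the published parameter set of the self-organizing
grid-cell model: 225 place-cell-like inputs with 5.4 cm Gaussian fields and
peak rate 20 projecting onto 100 grid cells in a 1 m square arena; adaptation
beta = 0.04, feedforward gain G = 0.1, recurrent gain 2, 60% of grid cells
active per step, rate-averaging delta = 0.5, rate-map time constant
tau = 0.03, 0.6 cm steps with 17 degree s.d. heading noise, 2e7 steps for a
full run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["SimulationConfig", "load_config", "save_config",
           "ARENA_SIDE", "PIXEL_SIZE", "N_PIXELS", "CROP_SLICE"]

ARENA_SIDE = 100.0          # cm
PIXEL_SIZE = 2.4            # cm; central 60 cm crop is exactly 25x25 pixels
N_PIXELS = 41               # full map, centered on the arena
CROP_SLICE = slice(8, 33)   # 25-pixel central square (plus/minus 30 cm)

ARCHITECTURES = ("torus2d", "ring1d", "stripe1dl", "fragmented", "none")


@dataclass
class SimulationConfig:
    """All model, trajectory and architecture parameters of one simulation."""

    n_input: int = 225                # input layer size (15 x 15 lattice)
    n_grid: int = 100                 # grid-cell layer size
    arena_side: float = ARENA_SIDE    # cm
    input_sigma: float = 5.4          # cm, Gaussian input field s.d.
    input_peak_rate: float = 20.0
    step_length: float = 0.6          # cm per simulation step
    turn_sd: float = 17.0             # degrees, heading increment s.d.
    n_steps: int = 20_000_000
    beta_adapt: float = 0.04
    gain_G: float = 0.1
    recurrent_gain: float = 2.0
    active_fraction: float = 0.6
    epsilon_learn: float = 0.005
    delta_avg: float = 0.5
    tau_map: float = 0.03
    architecture: str = "torus2d"
    kernel_spacing: float = 60.0      # cm, spacing of the toroidal kernel
    ring_spacing_deg: float = 3.6     # ring architecture neuron spacing
    ring_sigma_deg: float = 7.2       # ring architecture Gaussian s.d.
    fragment_repeats: int = 20        # fragmented architecture draws
    fragment_size: int = 10
    recurrent_scale: float = 1.0      # !=1 for strong/weak controls
    shuffle_recurrent: bool = False
    attractor_off_fraction: float | None = None  # zero W_rec at this fraction
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"architecture must be one of {ARCHITECTURES}, "
                f"got {self.architecture!r}")
        if not (0 < self.active_fraction <= 1):
            raise ValueError("active_fraction must be in (0, 1]")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        for name in ("arena_side", "input_sigma", "input_peak_rate",
                     "step_length", "gain_G", "tau_map"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.beta_adapt < 1):
            # beta = 0 is allowed only through adaptation_step directly
            if self.beta_adapt != 0:
                raise ValueError("beta_adapt must be in [0, 1)")
        if self.arena_side <= self.step_length:
            raise ValueError("arena must be larger than one step")

    @property
    def n_active(self) -> int:
        return int(np.ceil(self.active_fraction * self.n_grid))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> SimulationConfig:
    """Load a YAML/JSON config; missing keys take the published defaults,
    unknown keys are rejected, and an empty file yields the full default
    configuration."""
    with open(path) as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data)}")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
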