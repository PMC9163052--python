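"""Parameter bundles for the regulatory switches, signalling field, and simulator.

Defaults reproduce the published rate table of the model: a bistable
mutual-repression switch inside stem cells, a tristable
self-activation/mutual-repression switch inside progenitor cells, a
two-species mutually repressive signalling field secreted by the terminal
cell types, and per-cell division / death / transformation / movement rates.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields


class CellType(enum.IntEnum):
    """Integer codes used on the lattice and in snapshot files."""

    EMPTY = 0
    S = 1  # stem cell
    P = 2  # progenitor cell
    A = 3  # terminal type A (secretes signal S1)
    B = 4  # terminal type B (secretes signal S2)


#: Fate labels admissible for each switch system.
STEM_FATES = (CellType.S, CellType.P)
PROGENITOR_FATES = (CellType.P, CellType.A, CellType.B)


def _require_finite_positive(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class BistableParams:
    """Two-gene mutual-repression switch (stem cells).

    dx/dt = iota_x * beta^n / (beta^n + y^n) - gamma * x
    dy/dt = iota_y * beta^n / (beta^n + x^n) - gamma * y
    """

    iota_x: float = 85.0   # X synthesis rate (molecules / time), repressed by Y
    iota_y: float = 100.0  # Y synthesis rate, repressed by X
    beta: float = 45.0     # half-saturation constant (molecules)
    hill_n: float = 4.0    # Hill coefficient
    gamma: float = 1.0     # degradation rate (1 / time)

    def __post_init__(self):
        _require_finite_positive(self, ("iota_x", "iota_y", "beta", "hill_n", "gamma"))
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")


@dataclass(frozen=True)
class SignalEffectParams:
    """Saturating signal-effect coefficient: eps(s) = a*s/b for s <= b, else a."""

    a: float = 10.0  # saturation value added to the self-activation rate
    b: float = 15.0  # molecule count at which the effect saturates

    def __post_init__(self):
        _require_finite_positive(self, ("a", "b"))


@dataclass(frozen=True)
class TristableParams:
    """Two-gene self-activation + mutual-repression switch (progenitor cells).

    dx/dt = (alpha_x + eps_x) x^n/(beta^n + x^n) + iota_x beta^n/(beta^n + y^n) - gamma x
    and symmetrically for y.  ``eps_x``/``eps_y`` are the local signal-effect
    coefficients (0 in a signal-free medium).
    """

    alpha_x: float = 30.0
    alpha_y: float = 30.0
    iota_x: float = 30.0
    iota_y: float = 30.0
    beta: float = 47.5
    hill_n: float = 4.0
    gamma: float = 0.38
    eps_x: float = 0.0
    eps_y: float = 0.0

    def __post_init__(self):
        _require_finite_positive(
            self, ("alpha_x", "alpha_y", "iota_x", "iota_y", "beta", "hill_n", "gamma")
        )
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.eps_x < 0 or self.eps_y < 0:
            raise ValueError("signal-effect coefficients must be >= 0")

    def with_eps(self, eps_x: float, eps_y: float) -> "TristableParams":
        return TristableParams(
            self.alpha_x, self.alpha_y, self.iota_x, self.iota_y,
            self.beta, self.hill_n, self.gamma, eps_x, eps_y,
        )


@dataclass(frozen=True)
class SignalParams:
    """Reaction-diffusion parameters of the two signalling species.

    ds1/dt = D lap(s1) + alpha_1 beta^n/(beta^n + s2^n) - k s1   (and symmetrically)
    """

    D: float = 110.0      # diffusion coefficient (mesh area / time)
    k: float = 0.5        # decay rate (1 / time)
    alpha_1: float = 220.0
    alpha_2: float = 220.0
    beta: float = 2.0
    hill_n: float = 4.0
    h: float = 1.0        # mesh spacing

    def __post_init__(self):
        _require_finite_positive(self, ("D", "k", "alpha_1", "alpha_2", "beta", "hill_n", "h"))


@dataclass(frozen=True)
class SimConfig:
    """Full simulator configuration; defaults are the published rate table."""

    # stem-cell constant-rate channels
    r_s: float = 56.4        # division
    gamma_s: float = 0.0423  # death
    w_p: float = 0.329       # transformation S -> P
    m_s: float = 2.82        # movement
    # progenitor constant-rate channels
    r_p: float = 32.9
    gamma_p: float = 0.01504
    w_s: float = 0.1645      # transformation P -> S
    m_p: float = 0.94
    # terminal-cell death
    gamma_A: float = 0.003
    gamma_B: float = 0.0034

    stem: BistableParams = field(default_factory=BistableParams)
    progenitor: TristableParams = field(default_factory=TristableParams)
    signal: SignalParams = field(default_factory=SignalParams)
    signal_effect: SignalEffectParams = field(default_factory=SignalEffectParams)

    termination_divisions: float = 50.0  # stop when mean P-division counter reaches this
    n_shots: int = 500                   # snapshots retained per run
    seed: int = 0

    signals_enabled: bool = True
    #: rate-table fidelity switch: diffusion propensity is D/h^2 per occupied mesh
    #: (as printed); if True it is scaled by the molecule count instead.
    diffusion_scales_with_count: bool = False
    #: 'uniform' moves a molecule to a uniformly chosen orthogonal neighbour
    #: (physical diffusion); 'weighted' prefers neighbours that already hold
    #: more molecules, the uphill variant described alongside the rate table.
    diffusion_neighbor_rule: str = "uniform"
    #: calibration census for the density feedback iota_xs(n); None anchors it
    #: to the initial number of dividing cells.
    iota_calibration: int | None = None
    max_events: int = 2_000_000_000

    def __post_init__(self):
        rate_names = ("r_s", "gamma_s", "w_p", "m_s", "r_p", "gamma_p", "w_s", "m_p",
                      "gamma_A", "gamma_B")
        for name in rate_names:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"SimConfig.{name} must be finite and >= 0, got {v!r}")
        if self.termination_divisions < 1:
            raise ValueError("termination_divisions must be >= 1")
        if self.n_shots < 2:
            raise ValueError("n_shots must be >= 2")
        if self.diffusion_neighbor_rule not in ("uniform", "weighted"):
            raise ValueError("diffusion_neighbor_rule must be 'uniform' or 'weighted'")
        if self.iota_calibration is not None and self.iota_calibration < 1:
            raise ValueError("iota_calibration must be >= 1 when given")

    def replace(self, **kwargs) -> "SimConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return SimConfig(**current)
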