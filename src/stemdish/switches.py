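"""Deterministic dynamics and attractor analysis of the regulatory switches.

Three two-variable circuits drive the model: the stem-cell bistable
mutual-repression switch (attractors = fates S and P), the progenitor
tristable switch with self-activation (attractors = fates P, A, B), and the
mutually repressive signalling pair.  Fate calling is basin membership: a
daughter cell's determinant counts at birth are integrated under the
deterministic drift and the cell takes the label of the attractor reached.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from . import _kernel
from .params import (
    BistableParams,
    CellType,
    SignalEffectParams,
    SignalParams,
    TristableParams,
)

__all__ = [
    "stem_drift",
    "progenitor_drift",
    "signal_effect",
    "signal_reaction_rates",
    "find_fixed_points",
    "FixedPointSet",
    "classify_fate",
    "basin_map",
    "BasinMap",
    "sample_from_basin",
    "iota_xs_of_n",
]

#: side length of the cached basin grids (integer determinant counts 0..150)
BASIN_RESOLUTION = 151

#: a converged progenitor state whose smaller coordinate is below this count
#: is a dominant (A or B) attractor; the balanced attractor keeps both
#: determinants near or above the half-saturation constant (~47.5), so the
#: margin is wide.
_DOMINANT_LOSER_MAX = 10.0


def _check_state(x, y):
    if x < 0 or y < 0:
        raise ValueError(f"determinant counts must be >= 0, got ({x}, {y})")


def stem_drift(x: float, y: float, p: BistableParams | None = None):
    """Right-hand side of the bistable stem switch at state (x, y)."""
    p = p or BistableParams()
    _check_state(x, y)
    bn = p.beta ** p.hill_n
    fx = p.iota_x * bn / (bn + y ** p.hill_n) - p.gamma * x
    fy = p.iota_y * bn / (bn + x ** p.hill_n) - p.gamma * y
    return fx, fy


def progenitor_drift(x: float, y: float, p: TristableParams | None = None):
    """Right-hand side of the tristable progenitor switch at state (x, y)."""
    p = p or TristableParams()
    _check_state(x, y)
    bn = p.beta ** p.hill_n
    xn = x ** p.hill_n
    yn = y ** p.hill_n
    fx = (p.alpha_x + p.eps_x) * xn / (bn + xn) + p.iota_x * bn / (bn + yn) - p.gamma * x
    fy = (p.alpha_y + p.eps_y) * yn / (bn + yn) + p.iota_y * bn / (bn + xn) - p.gamma * y
    return fx, fy


def signal_effect(s: float, p: SignalEffectParams | None = None) -> float:
    """Saturating signal-effect coefficient: a*s/b for s <= b, else a."""
    p = p or SignalEffectParams()
    if s < 0:
        raise ValueError(f"signal count must be >= 0, got {s}")
    return p.a * s / p.b if s <= p.b else p.a


def signal_reaction_rates(s1: float, s2: float, p: SignalParams | None = None):
    """Per-mesh production and decay rates of the two signal species.

    Diffusion is a separate transport channel handled by the SSA engine;
    returns (prod1, deg1, prod2, deg2).
    """
    p = p or SignalParams()
    if s1 < 0 or s2 < 0:
        raise ValueError("signal counts must be >= 0")
    bn = p.beta ** p.hill_n
    prod1 = p.alpha_1 * bn / (bn + s2 ** p.hill_n)
    prod2 = p.alpha_2 * bn / (bn + s1 ** p.hill_n)
    return prod1, p.k * s1, prod2, p.k * s2


# ---------------------------------------------------------------------------
# fixed points

@dataclass(frozen=True)
class FixedPointSet:
    """Fixed points of a two-variable switch with per-point stability flags."""

    points: tuple[tuple[float, float], ...]
    stable: tuple[bool, ...]

    @property
    def stable_points(self) -> tuple[tuple[float, float], ...]:
        return tuple(pt for pt, st in zip(self.points, self.stable) if st)


def _drift_and_jacobian(system: str, params):
    if system == "stem":
        p = params or BistableParams()

        def fun(v):
            return stem_drift(max(v[0], 0.0), max(v[1], 0.0), p)

        def jac(v):
            x, y = max(v[0], 0.0), max(v[1], 0.0)
            n, bn, g = p.hill_n, p.beta ** p.hill_n, p.gamma
            dxy = -p.iota_x * bn * n * y ** (n - 1) / (bn + y ** n) ** 2
            dyx = -p.iota_y * bn * n * x ** (n - 1) / (bn + x ** n) ** 2
            return np.array([[-g, dxy], [dyx, -g]])

        return fun, jac
    if system == "progenitor":
        p = params or TristableParams()

        def fun(v):
            return progenitor_drift(max(v[0], 0.0), max(v[1], 0.0), p)

        def jac(v):
            x, y = max(v[0], 0.0), max(v[1], 0.0)
            n, bn, g = p.hill_n, p.beta ** p.hill_n, p.gamma
            xn, yn = x ** n, y ** n
            dxx = (p.alpha_x + p.eps_x) * n * bn * x ** (n - 1) / (bn + xn) ** 2 - g
            dxy = -p.iota_x * bn * n * y ** (n - 1) / (bn + yn) ** 2
            dyx = -p.iota_y * bn * n * x ** (n - 1) / (bn + xn) ** 2
            dyy = (p.alpha_y + p.eps_y) * n * bn * y ** (n - 1) / (bn + yn) ** 2 - g
            return np.array([[dxx, dxy], [dyx, dyy]])

        return fun, jac
    if system == "signal":
        p = params or SignalParams()

        def fun(v):
            s1, s2 = max(v[0], 0.0), max(v[1], 0.0)
            prod1, deg1, prod2, deg2 = signal_reaction_rates(s1, s2, p)
            return prod1 - deg1, prod2 - deg2

        def jac(v):
            s1, s2 = max(v[0], 0.0), max(v[1], 0.0)
            n, bn = p.hill_n, p.beta ** p.hill_n
            d12 = -p.alpha_1 * bn * n * s2 ** (n - 1) / (bn + s2 ** n) ** 2
            d21 = -p.alpha_2 * bn * n * s1 ** (n - 1) / (bn + s1 ** n) ** 2
            return np.array([[-p.k, d12], [d21, -p.k]])

        return fun, jac
    raise ValueError(f"unknown system {system!r}; expected 'stem', 'progenitor' or 'signal'")


def find_fixed_points(system: str, params=None, extent: float | None = None,
                      n_seeds: int = 13) -> FixedPointSet:
    """Locate all non-negative fixed points of a switch by multi-start rooting.

    Stability is judged by the eigenvalues of the analytic 2x2 Jacobian.
    """
    fun, jac = _drift_and_jacobian(system, params)
    if extent is None:
        extent = 900.0 if system == "signal" else 200.0
    pts: list[tuple[float, float]] = []
    stable: list[bool] = []
    for sx in np.linspace(0.0, extent, n_seeds):
        for sy in np.linspace(0.0, extent, n_seeds):
            sol = root(fun, np.array([sx, sy]), method="hybr")
            if not sol.success:
                continue
            x, y = sol.x
            if x < -1e-8 or y < -1e-8:
                continue
            x, y = max(x, 0.0), max(y, 0.0)
            if any((x - px) ** 2 + (y - py) ** 2 < 0.25 for px, py in pts):
                continue
            eig = np.linalg.eigvals(jac((x, y)))
            pts.append((x, y))
            stable.append(bool(np.all(eig.real < 0)))
    order = np.lexsort(([p[1] for p in pts], [p[0] for p in pts]))
    return FixedPointSet(points=tuple(pts[i] for i in order),
                         stable=tuple(stable[i] for i in order))


def _label_stem_fp(x: float, y: float) -> CellType:
    return CellType.S if x > y else CellType.P


def _label_prog_fp(x: float, y: float) -> CellType:
    if min(x, y) < _DOMINANT_LOSER_MAX:
        return CellType.A if x > y else CellType.B
    return CellType.P


@functools.lru_cache(maxsize=64)
def _stable_fp_arrays(system: str, params):
    """(fps, labels) arrays for the jit classifier; labels are CellType codes."""
    fset = find_fixed_points(system, params)
    pts = fset.stable_points
    if not pts:
        raise RuntimeError(f"no stable fixed point found for the {system} switch")
    fps = np.array(pts, dtype=np.float64)
    if system == "stem":
        labels = np.array([_label_stem_fp(x, y) for x, y in pts], dtype=np.int8)
    else:
        labels = np.array([_label_prog_fp(x, y) for x, y in pts], dtype=np.int8)
    return fps, labels


def classify_fate(x: float, y: float, system: str, params=None) -> CellType:
    """Fate of a cell born with determinant counts (x, y).

    Integrates the deterministic drift (RK4, dt=0.01) until the trajectory
    enters the unit ball of a stable fixed point; stalls on a separatrix fall
    back to the dividing fate P.  Stem system returns S or P; progenitor
    system returns P, A or B.
    """
    _check_state(x, y)
    if system == "stem":
        p = params or BistableParams()
        fps, labels = _stable_fp_arrays("stem", p)
        lab = _kernel.classify_stem(float(x), float(y), p.iota_x, p.iota_y,
                                    p.beta ** p.hill_n, p.hill_n, p.gamma, fps, labels)
    elif system == "progenitor":
        p = params or TristableParams()
        fps, labels = _stable_fp_arrays("progenitor", p)
        lab = _kernel.classify_prog(float(x), float(y), p.alpha_x, p.alpha_y,
                                    p.iota_x, p.iota_y, p.beta ** p.hill_n,
                                    p.hill_n, p.gamma, p.eps_x, p.eps_y,
                                    fps, fps.shape[0], labels)
    else:
        raise ValueError("classify_fate supports the 'stem' and 'progenitor' systems")
    return CellType(int(lab))


@dataclass(frozen=True)
class BasinMap:
    """Cached attractor-basin labels on an integer determinant grid.

    ``labels[i, j]`` is the CellType code of the basin containing the state
    (x=i, y=j); the grid covers 0..resolution-1 in unit steps.
    """

    system: str
    labels: np.ndarray  # int8 (res, res)
    fixed_points: np.ndarray  # float64 (k, 2), stable points only
    fp_labels: np.ndarray  # int8 (k,)

    @property
    def resolution(self) -> int:
        return self.labels.shape[0]

    def label_counts(self) -> dict[CellType, int]:
        vals, cnts = np.unique(self.labels, return_counts=True)
        return {CellType(int(v)): int(c) for v, c in zip(vals, cnts)}

    def to_text(self, path) -> None:
        np.savetxt(path, self.labels, fmt="%d",
                   header=f"system={self.system} resolution={self.resolution}")


def basin_map(system: str, params=None, resolution: int = BASIN_RESOLUTION) -> BasinMap:
    """Exhaustive basin classification of the integer grid [0, res)^2."""
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if system == "stem":
        p = params or BistableParams()
        fps, labels = _stable_fp_arrays("stem", p)
        grid = _kernel.build_stem_map(resolution, p.iota_x, p.iota_y,
                                      p.beta ** p.hill_n, p.hill_n, p.gamma,
                                      fps, labels)
    elif system == "progenitor":
        p = params or TristableParams()
        fps, labels = _stable_fp_arrays("progenitor", p)
        grid = _kernel.build_prog_map(resolution, p.alpha_x, p.alpha_y, p.iota_x,
                                      p.iota_y, p.beta ** p.hill_n, p.hill_n,
                                      p.gamma, p.eps_x, p.eps_y,
                                      fps, fps.shape[0], labels)
    else:
        raise ValueError("basin_map supports the 'stem' and 'progenitor' systems")
    return BasinMap(system=system, labels=grid, fixed_points=fps, fp_labels=labels)


def sample_from_basin(bmap: BasinMap, label: CellType, rng: np.random.Generator):
    """Integer determinant state drawn uniformly from a basin's grid points."""
    rows, cols = np.nonzero(bmap.labels == int(label))
    if rows.size == 0:
        raise ValueError(f"basin for {label!r} is empty on the sampled grid")
    i = rng.integers(rows.size)
    return int(rows[i]), int(cols[i])


def iota_xs_of_n(n_total: float, base: float = 85.0, scale: float = 100.0) -> float:
    """Density feedback on the stem X synthesis rate.

    A strictly decreasing hyperbola equal to ``base`` at the calibration
    census ``scale``: 2*base*scale / (scale + n).  Below the calibration
    census the rate rises (up to 2*base at an empty dish), boosting symmetric
    S+S renewal when dividing cells are scarce; above it, renewal becomes
    rarer.  The model requires only a negative derivative; this hyperbolic
    form is the package's choice and mirrors the compiled engine.
    """
    if n_total < 0:
        raise ValueError("dividing-cell count must be >= 0")
    if base <= 0 or scale <= 0:
        raise ValueError("base rate and calibration scale must be > 0")
    return base * 2.0 * scale / (scale + n_total)
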