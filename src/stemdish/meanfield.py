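"""Deterministic population-level model of the four cell-type densities.

The dish dynamics average to a linear ODE system for the densities
(n_S, n_P, n_A, n_B) driven by fifteen effective rates: three stem division
modes (eta: S->S+P, eta_S: S->S+S, eta_P: S->P+P), the S<->P transformation
rates (w_P, w_S), six progenitor division modes (lambda_P: P->P+P,
lambda_A: P->A+P, lambda_B: P->B+P, mu_d: P->A+B, mu_A: P->A+A,
mu_B: P->B+B) and four death rates.  The dividing subsystem (n_S, n_P)
decouples from the terminal one (n_A, n_B); homeostasis requires the
density feedback eta_S'(n) < 0, under which the closed-form determinant/trace
criteria below certify stability of the coexistence fixed point.

These rates are not inputs of the simulator — they emerge from the switch
basins — so the module also estimates them from a simulation's event log
(:func:`measure_effective_rates`), closing the loop between the two levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RateParams",
    "DensityState",
    "StabilityReport",
    "ode_rhs",
    "steady_state",
    "check_conditions",
    "stability",
    "numerical_jacobian",
    "measure_effective_rates",
]


@dataclass(frozen=True)
class RateParams:
    """Effective per-cell rates of the population-level model."""

    eta: float = 0.0       # S -> S + P
    eta_S: float = 0.0     # S -> S + S
    eta_P: float = 0.0     # S -> P + P
    w_S: float = 0.0       # P -> S
    w_P: float = 0.0       # S -> P
    gamma_S: float = 0.0
    gamma_P: float = 0.0
    lambda_P: float = 0.0  # P -> P + P
    lambda_A: float = 0.0  # P -> A + P
    lambda_B: float = 0.0  # P -> B + P
    mu_d: float = 0.0      # P -> A + B
    mu_A: float = 0.0      # P -> A + A
    mu_B: float = 0.0      # P -> B + B
    gamma_A: float = 0.0
    gamma_B: float = 0.0
    #: derivative of eta_S with respect to the dividing density n at the
    #: evaluation point (the density feedback; <= 0)
    eta_S_slope: float = 0.0

    def __post_init__(self):
        for name in ("eta", "eta_S", "eta_P", "w_S", "w_P", "gamma_S", "gamma_P",
                     "lambda_P", "lambda_A", "lambda_B", "mu_d", "mu_A", "mu_B",
                     "gamma_A", "gamma_B"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"RateParams.{name} must be finite and >= 0, got {v!r}")
        if self.eta_S_slope > 0:
            raise ValueError("eta_S_slope must be <= 0")

    def replace(self, **kw) -> "RateParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class DensityState:
    """Non-negative densities of the four cell types."""

    n_S: float
    n_P: float
    n_A: float
    n_B: float

    def __post_init__(self):
        for name in ("n_S", "n_P", "n_A", "n_B"):
            if getattr(self, name) < 0:
                raise ValueError(f"DensityState.{name} must be >= 0")

    @property
    def n(self) -> float:
        """Total dividing density."""
        return self.n_S + self.n_P

    def as_array(self) -> np.ndarray:
        return np.array([self.n_S, self.n_P, self.n_A, self.n_B])


def ode_rhs(state: DensityState | np.ndarray, p: RateParams,
            n_ref: float | None = None) -> np.ndarray:
    """Time derivatives (dn_S, dn_P, dn_A, dn_B).

    With ``n_ref`` given, the stem self-renewal rate carries the density
    feedback eta_S(n) = eta_S + eta_S_slope * (n - n_ref), anchored so that
    eta_S(n_ref) equals the nominal value.
    """
    if isinstance(state, DensityState):
        v = state.as_array()
    else:
        v = np.asarray(state, dtype=float)
    n_S, n_P, n_A, n_B = v
    eta_S = p.eta_S
    if n_ref is not None:
        eta_S = p.eta_S + p.eta_S_slope * ((n_S + n_P) - n_ref)
    d_S = n_S * eta_S - n_S * p.eta_P + n_P * p.w_S - n_S * p.w_P - n_S * p.gamma_S
    d_P = (n_S * p.eta + 2 * n_S * p.eta_P + n_S * p.w_P - n_P * p.w_S
           - n_P * p.gamma_P - n_P * (-p.lambda_P + p.mu_d + p.mu_A + p.mu_B))
    d_A = n_P * (p.lambda_A + p.mu_d + 2 * p.mu_A) - n_A * p.gamma_A
    d_B = n_P * (p.lambda_B + p.mu_d + 2 * p.mu_B) - n_B * p.gamma_B
    return np.array([d_S, d_P, d_A, d_B])


def steady_state(p: RateParams, n_P_ref: float):
    """Coexistence fixed point scaled to a reference progenitor density.

    The dividing subsystem fixes only ratios, so the absolute scale comes
    from ``n_P_ref``.  Returns ``(state, w_S_star)`` where ``w_S_star`` is
    the transformation rate that balances the subsystem; the state is a fixed
    point of :func:`ode_rhs` evaluated with ``w_S = w_S_star``.
    """
    if n_P_ref <= 0:
        raise ValueError("n_P_ref must be > 0")
    if p.gamma_A <= 0 or p.gamma_B <= 0:
        raise ValueError("terminal death rates must be > 0 for a finite fixed point")
    kappa = p.eta_S - p.eta_P - p.gamma_S - p.w_P
    denom = p.eta + p.eta_P + p.eta_S - p.gamma_S
    if kappa == 0 or denom == 0:
        raise ZeroDivisionError("degenerate rates: zero denominator in the fixed point")
    w_S_star = kappa * (-p.gamma_P + p.lambda_P - p.mu_d - p.mu_A - p.mu_B) / denom
    n_S = n_P_ref * (-w_S_star) / kappa
    n_A = n_P_ref * (p.lambda_A + p.mu_d + 2 * p.mu_A) / p.gamma_A
    n_B = n_P_ref * (p.lambda_B + p.mu_d + 2 * p.mu_B) / p.gamma_B
    return DensityState(n_S, n_P_ref, n_A, n_B), w_S_star


def check_conditions(p: RateParams) -> tuple[bool, bool, bool]:
    """The three closed-form parameter-regime conditions.

    The first guarantees positivity of the dividing fixed point; exactly one
    of the remaining two must hold for the balancing rate w_S* to be
    positive.  The homeostatic regime of the model (progenitors with limited
    proliferative capacity) is the first together with the third.
    """
    cond9 = p.eta_S - p.eta_P - p.gamma_S - p.w_P < 0
    lhs = p.eta + p.eta_P + p.eta_S
    rhs = p.gamma_P + p.mu_d + p.mu_A + p.mu_B
    cond10 = (lhs < p.gamma_S) and (p.lambda_P > rhs)
    cond11 = (lhs > p.gamma_S) and (p.lambda_P < rhs)
    return cond9, cond10, cond11


@dataclass(frozen=True)
class StabilityReport:
    fixed_point: DensityState
    condition_9: bool
    condition_10: bool
    condition_11: bool
    det_J: float           # determinant of the reduced dividing-block Jacobian
    tr_J: float            # trace of the reduced dividing-block Jacobian
    terminal_eigenvalues: tuple[float, float]
    eigenvalues: np.ndarray  # full 4x4 numerical spectrum
    stable: bool


def numerical_jacobian(p: RateParams, fp: DensityState, h: float = 1e-6) -> np.ndarray:
    """Central-difference 4x4 Jacobian of the rhs (with density feedback)
    at the fixed point."""
    v0 = fp.as_array()
    J = np.zeros((4, 4))
    for j in range(4):
        dv = np.zeros(4)
        dv[j] = h * max(1.0, abs(v0[j]))
        J[:, j] = (ode_rhs(v0 + dv, p, n_ref=fp.n)
                   - ode_rhs(v0 - dv, p, n_ref=fp.n)) / (2 * dv[j])
    return J


def stability(p: RateParams, fp: DensityState, residual_tol: float = 1e-8) -> StabilityReport:
    """Closed-form stability verdict at a coexistence fixed point.

    ``p.w_S`` must already hold the balancing value w_S* (see
    :func:`steady_state`); the fixed point is re-checked against the rhs.
    The dividing block is judged by det = zeta * n * eta_S'(n) > 0 and the
    closed-form trace < 0; the terminal block contributes eigenvalues
    (-gamma_A, -gamma_B).
    """
    res = ode_rhs(fp, p, n_ref=fp.n)
    scale = max(1.0, float(np.max(np.abs(fp.as_array()))))
    if np.max(np.abs(res)) > residual_tol * scale:
        raise ValueError(f"state is not a fixed point (residual {res})")
    zeta = (-p.w_S - p.gamma_P - p.w_P - p.eta + p.lambda_P
            - p.mu_d - p.mu_A - p.mu_B - 2 * p.eta_P)
    det_J = zeta * fp.n * p.eta_S_slope
    tr_J = (-p.w_S + (p.eta_S - p.eta_P - p.gamma_S - p.w_P)
            + (p.lambda_P - p.gamma_P - p.mu_d - p.mu_A - p.mu_B))
    cond9, cond10, cond11 = check_conditions(p)
    eig = np.linalg.eigvals(numerical_jacobian(p, fp))
    stable = (det_J > 0) and (tr_J < 0) and (p.gamma_A > 0) and (p.gamma_B > 0)
    return StabilityReport(
        fixed_point=fp,
        condition_9=cond9,
        condition_10=cond10,
        condition_11=cond11,
        det_J=det_J,
        tr_J=tr_J,
        terminal_eigenvalues=(-p.gamma_A, -p.gamma_B),
        eigenvalues=eig,
        stable=stable,
    )


# ---------------------------------------------------------------------------
# bridging the simulator to the effective rates

#: (counter key, exposure key) per RateParams field
_RATE_SOURCES = {
    "eta": ("eta", "S"),
    "eta_S": ("eta_S", "S"),
    "eta_P": ("eta_P", "S"),
    "w_P": ("w_P", "S"),
    "gamma_S": ("gamma_S", "S"),
    "w_S": ("w_S", "P"),
    "gamma_P": ("gamma_P", "P"),
    "lambda_P": ("lambda_P", "P"),
    "lambda_A": ("lambda_A", "P"),
    "lambda_B": ("lambda_B", "P"),
    "mu_d": ("mu_d", "P"),
    "mu_A": ("mu_A", "P"),
    "mu_B": ("mu_B", "P"),
    "gamma_A": ("gamma_A", "A"),
    "gamma_B": ("gamma_B", "B"),
}


def measure_effective_rates(log) -> tuple[RateParams, dict[str, float]]:
    """Maximum-likelihood constant-rate estimates from an event log.

    Each per-cell channel rate is (event count) / (integrated cell-time of
    the firing compartment); the Poisson standard error is sqrt(count) /
    exposure (one waiting-time scale when the count is zero).  Raises if a
    needed compartment never accumulated exposure.
    """
    rates: dict[str, float] = {}
    se: dict[str, float] = {}
    for field_name, (ckey, ekey) in _RATE_SOURCES.items():
        exp_time = log.exposure.get(ekey, 0.0)
        count = log.counts.get(ckey, 0)
        if exp_time <= 0:
            if count:
                raise ValueError(f"events of {ckey!r} with zero {ekey}-exposure")
            rates[field_name] = 0.0
            se[field_name] = float("inf")
            continue
        rates[field_name] = count / exp_time
        se[field_name] = math.sqrt(max(count, 1)) / exp_time
    return RateParams(**rates), se
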