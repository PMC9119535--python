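"""Right-hand side of the coupled coral-symbiont-trait model.

The model couples three state variables: coral abundance C (cm^2),
symbiont abundance S (cells), and the community-mean energy-investment
trait U.  Corals grow logistically at a temperature-limited rate weighted
by the symbiotic feedback, pay an investment-dependent symbiotic cost and
a background mortality; symbionts grow logistically with a carrying
capacity proportional to coral abundance; the trait climbs the coral
fitness gradient at the speed of acclimation N:

    dC/dt = F(U,S,C) * C
    dS/dt = G_S(T) * (1 - S/K_S(C)) * S
    dU/dt = N * dF/dU

with fitness

    F = G_C(T) * kappa(S) * E(U) * (1 - C/K_C) - mu(U,S) - M_C
    kappa * E = S/(Gamma_h*C + S) * (1 - exp(-beta*U))
    mu = alpha * exp(r*U) * S/K_S

The temperature dependence of coral growth is a skew-normal occurrence
curve normalised to its mode, G_C(T) = G_max * G(T)/max_T G(T) with
G(T) = phi((T-T_bar)/sigma) * Phi(s*(T-T_bar)/sigma).

All functions here evaluate in natural units and accept scalars or numpy
arrays.  The trait gradient is the closed-form derivative of F; a
finite-difference version exists only in the test-suite as an oracle.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

from .params import Derivatives, GlobalParams, ModelState, RegionParams

__all__ = [
    "growth_curve",
    "max_growth_location",
    "coral_growth_rate",
    "symbiont_growth_rate",
    "symbiont_capacity",
    "symbiotic_feedback",
    "symbiotic_cost",
    "coral_fitness",
    "fitness_gradient",
    "rhs",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _phi(z):
    """Standard normal density."""
    return np.exp(-0.5 * np.asarray(z, dtype=float) ** 2) / _SQRT_2PI


def growth_curve(T, region: RegionParams):
    """Unnormalised skew-normal thermal occurrence curve G(T).

    G(T) = phi((T-T_bar)/sigma) * Phi(s*(T-T_bar)/sigma); non-negative and
    vanishing far from T_bar.  ``s`` > 0 skews the curve toward warmer
    temperatures.
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    z = (T - region.T_bar) / region.sigma
    out = _phi(z) * ndtr(region.skew_s * z)
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=None)
def _mode_cached(T_bar: float, sigma: float, skew_s: float) -> tuple[float, float]:
    region = _BareCurve(T_bar, sigma, skew_s)
    lo, hi = T_bar - 6.0 * sigma, T_bar + 6.0 * sigma
    grid = np.linspace(lo, hi, 241)
    vals = growth_curve(grid, region)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda t: -growth_curve(t, region),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-3},
    )
    T_mode = float(res.x)
    return T_mode, float(growth_curve(T_mode, region))


class _BareCurve:
    """Minimal stand-in carrying only the curve parameters (for caching)."""

    __slots__ = ("T_bar", "sigma", "skew_s")

    def __init__(self, T_bar: float, sigma: float, skew_s: float) -> None:
        self.T_bar = T_bar
        self.sigma = sigma
        self.skew_s = skew_s


def max_growth_location(region: RegionParams) -> tuple[float, float]:
    """(T_mode, G_peak): location and height of the curve's maximum.

    The skew-normal mode has no closed form; it is located by golden-
    section/parabolic refinement of a coarse grid over T_bar +/- 6 sigma
    (final tolerance 1e-3 deg C) and cached per parameter triple.  The
    peak value is evaluated at the located mode, so the normalised growth
    rate equals G_max there by construction.
    """
    return _mode_cached(region.T_bar, region.sigma, region.skew_s)


def coral_growth_rate(T, region: RegionParams, params: GlobalParams = GlobalParams()):
    """Temperature-limited coral growth rate G_C(T) = G_max*G(T)/G_peak."""
    _, G_peak = max_growth_location(region)
    return params.G_max * growth_curve(T, region) / G_peak


def symbiont_growth_rate(T, params: GlobalParams = GlobalParams()):
    """Symbiont thermal growth envelope G_S(T) = a*exp(b*T), month^-1."""
    return params.a * np.exp(params.b * np.asarray(T, dtype=float))


def symbiont_capacity(C, params: GlobalParams = GlobalParams()):
    """Symbiont carrying capacity K_S = K_smax * C (cells)."""
    return params.K_smax * np.asarray(C, dtype=float)


def _guard(region: RegionParams, params: GlobalParams, eps: float) -> float:
    """Denominator guard in natural units.

    eps is expressed in the nondimensional units of the integrator (S and
    K_S scaled by K_smax*K_C), so the natural-unit guard added to both
    Gamma_h*C + S and K_S is eps * K_smax * K_C.  This matches the scaled
    kernel exactly.
    """
    return eps * params.K_smax * region.K_C


def symbiotic_feedback(
    S,
    C,
    U,
    params: GlobalParams = GlobalParams(),
    region: RegionParams | None = None,
    eps: float = 0.0,
):
    """Symbiotic feedback kappa(S)*E(U) in [0, 1).

    Zero without symbionts or without energy investment; increasing and
    saturating in both S and U.  ``eps`` adds the scaled denominator guard
    (requires ``region`` when non-zero).
    """
    S = np.asarray(S, dtype=float)
    C = np.asarray(C, dtype=float)
    U = np.asarray(U, dtype=float)
    guard = _guard(region, params, eps) if eps else 0.0
    denom = params.Gamma_h * C + S + guard
    kappa = np.divide(S, denom, out=np.zeros_like(S + denom), where=denom > 0)
    E = 1.0 - np.exp(-params.beta * U)
    out = kappa * E
    return float(out) if out.ndim == 0 else out


def symbiotic_cost(
    U,
    S,
    C,
    params: GlobalParams = GlobalParams(),
    region: RegionParams | None = None,
    eps: float = 0.0,
):
    """Cost of symbiosis mu(U,S) = alpha*exp(r*U)*S/K_S, month^-1."""
    S = np.asarray(S, dtype=float)
    U = np.asarray(U, dtype=float)
    K_S = symbiont_capacity(C, params) + (_guard(region, params, eps) if eps else 0.0)
    ratio = np.divide(S, K_S, out=np.zeros_like(S + K_S), where=K_S > 0)
    out = params.alpha * np.exp(params.r * U) * ratio
    return float(out) if out.ndim == 0 else out


def coral_fitness(
    state: ModelState,
    T: float,
    region: RegionParams,
    params: GlobalParams = GlobalParams(),
    eps: float = 0.0,
):
    """Per-capita coral growth rate F(U,S,C), month^-1.

    Equals -M_C without symbionts; bounded above by G_max - M_C.
    """
    gross = (
        coral_growth_rate(T, region, params)
        * symbiotic_feedback(state.S, state.C, state.U, params, region, eps)
        * (1.0 - state.C / region.K_C)
    )
    return gross - symbiotic_cost(state.U, state.S, state.C, params, region, eps) - params.M_C


def fitness_gradient(
    state: ModelState,
    T: float,
    region: RegionParams,
    params: GlobalParams = GlobalParams(),
    eps: float = 0.0,
):
    """Closed-form trait derivative dF/dU of the coral fitness.

    dF/dU = G_C * kappa * (1 - C/K_C) * beta * exp(-beta U)
            - alpha * r * exp(r U) * S/K_S

    This is the analytic differentiation of F; it vanishes when S = 0
    (no symbionts, no selective pressure on the investment trait).
    """
    guard = _guard(region, params, eps) if eps else 0.0
    denom = params.Gamma_h * state.C + state.S + guard
    kappa = state.S / denom if denom > 0 else 0.0
    K_S = symbiont_capacity(state.C, params) + guard
    ratio = state.S / K_S if K_S > 0 else 0.0
    benefit = (
        coral_growth_rate(T, region, params)
        * kappa
        * (1.0 - state.C / region.K_C)
        * params.beta
        * math.exp(-params.beta * state.U)
    )
    cost = params.alpha * params.r * math.exp(params.r * state.U) * ratio
    return benefit - cost


def rhs(
    state: ModelState,
    T: float,
    region: RegionParams,
    params: GlobalParams = GlobalParams(),
    eps: float = 0.0,
) -> Derivatives:
    """Full model right-hand side in natural units.

    dC/dt = F*C; dS/dt = G_S*(1 - S/K_S)*S; dU/dt = N*dF/dU.  On the
    non-negative orthant's boundary the flow never points outward, so the
    exact dynamics preserve non-negativity.
    """
    F = coral_fitness(state, T, region, params, eps)
    guard = _guard(region, params, eps) if eps else 0.0
    K_S = symbiont_capacity(state.C, params) + guard
    ratio = state.S / K_S if K_S > 0 else 0.0
    dS = symbiont_growth_rate(T, params) * (1.0 - ratio) * state.S
    dU = region.N * fitness_gradient(state, T, region, params, eps)
    return Derivatives(dC_dt=F * state.C, dS_dt=float(dS), dU_dt=float(dU))
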