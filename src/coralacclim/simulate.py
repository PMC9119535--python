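"""Integration protocols: spin-up, forced runs, and derived metrics.

The integrator works in nondimensional variables

    c = C / K_C,    s = S / (K_smax * K_C),    u = U (unscaled),

because C (~1e15 cm^2) and U (~1e-7 trait units) differ by over twenty
orders of magnitude; the scaling keeps the Runge-Kutta arithmetic well
conditioned.  In scaled variables the system reads

    dc/dt = F * c,                      F = gC*kappa*E*(1-c) - mu - M_C
    ds/dt = gS * (1 - s/(c+eps)) * s,   kappa = s/(gamma*c + s + eps)
    du/dt = N * (gC*kappa*(1-c)*beta*e^{-beta u} - alpha*r*e^{r u}*s/(c+eps))

with gamma = Gamma_h/K_smax and a small guard eps added to the
denominators to prevent division by zero.  Natural units are restored on
output.

The default integrator is classical RK4 with a fixed number of substeps
per month and piecewise-constant monthly forcing; an adaptive alternative
(scipy LSODA) exists for verification.  The monthly loop is compiled with
numba when available; the pure-Python path runs the identical code.

Protocol: a run first evaluates the bleaching condition for the month (an
instantaneous reduction of S drawn from the region's exceedance band),
then integrates the ODEs across the month at that month's temperature.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core
from .bleaching import BleachingEvent, draw_monthly_reductions
from .forcing import TemperatureSeries
from .params import GlobalParams, ModelState, RegionParams

logger = logging.getLogger(__name__)

__all__ = [
    "RunSettings",
    "Trajectory",
    "spin_up",
    "run",
    "relative_abundance",
    "decline_metric",
    "trait_change_metric",
    "scaled_rhs_norm",
    "SPINUP_YEARS",
    "DEFAULT_INITIAL_CONDITIONS",
]

#: Published protocol constants: spin-up duration and initial conditions
#: (C as a fraction of K_C; S in cells; U in trait units).
SPINUP_YEARS = 2000
DEFAULT_INITIAL_CONDITIONS = {"C_frac": 0.75, "S": 1e-3, "U": 5e-7}


@dataclass(frozen=True)
class RunSettings:
    """Numerical settings for a simulation.

    substeps_per_month : RK4 substeps per month (default 10).
    integrator : 'rk4' (fixed-step, default) or 'adaptive' (LSODA).
    bleaching_enabled : whether the stochastic event process is active.
    seed : seed of the isolated bleaching random stream.
    epsilon_guard : denominator guard in scaled units.
    clip_tol : largest tolerated negative excursion (scaled) before a
        hard error; smaller excursions are clipped to zero and logged.
    """

    substeps_per_month: int = 10
    integrator: str = "rk4"
    bleaching_enabled: bool = True
    seed: int = 0
    epsilon_guard: float = 1e-12
    clip_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.substeps_per_month < 1:
            raise ValueError("substeps_per_month must be >= 1")
        if self.integrator not in ("rk4", "adaptive"):
            raise ValueError("integrator must be 'rk4' or 'adaptive'")


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed model output of one forced run.

    ``C_series``/``S_series``/``U_series`` hold the state at month
    boundaries and have length ``n_months + 1``: index 0 is the initial
    state, index m is the state after integrating month m-1.  Bleaching
    discontinuities happen between index m and the integration of month m
    and are recorded in ``events`` (S_before refers to ``S_series[m]``).
    """

    start: tuple[int, int]
    T: np.ndarray
    C_series: np.ndarray
    S_series: np.ndarray
    U_series: np.ndarray
    events: tuple[BleachingEvent, ...]
    region: str = ""

    def __post_init__(self) -> None:
        n = len(self.T)
        for name in ("C_series", "S_series", "U_series"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size != n + 1:
                raise ValueError(f"{name} must have length n_months+1 = {n + 1}")
        object.__setattr__(self, "events", tuple(self.events))
        for ev in self.events:
            if not (0 <= ev.time < n):
                raise ValueError(f"event month {ev.time} outside run range")

    @property
    def n_months(self) -> int:
        return len(self.T)

    @property
    def times(self) -> np.ndarray:
        """Month indices 0..n_months for the state samples."""
        return np.arange(self.n_months + 1)

    def sample_years(self) -> np.ndarray:
        """Calendar year of each end-of-month state sample (length n_months)."""
        y0, m0 = self.start
        o = y0 * 12 + (m0 - 1) + np.arange(self.n_months)
        return o // 12

    def final_state(self) -> ModelState:
        return ModelState(
            C=float(self.C_series[-1]),
            S=float(self.S_series[-1]),
            U=float(self.U_series[-1]),
            t=float(self.n_months),
        )

    def to_dataframe(self, K_C: float | None = None) -> pd.DataFrame:
        """Monthly table: forcing, end-of-month state, bleaching flag."""
        y0, m0 = self.start
        o = y0 * 12 + (m0 - 1) + np.arange(self.n_months)
        bleached = np.zeros(self.n_months, dtype=bool)
        for ev in self.events:
            bleached[ev.time] = True
        df = pd.DataFrame(
            {
                "month_index": np.arange(self.n_months),
                "year": o // 12,
                "month": o % 12 + 1,
                "T_c": self.T,
                "C_cm2": self.C_series[1:],
                "S_cells": self.S_series[1:],
                "U_trait": self.U_series[1:],
                "bleached_flag": bleached,
            }
        )
        if K_C is not None:
            df.insert(7, "C_rel_pct", 100.0 * df["C_cm2"] / K_C)
        return df


# ---------------------------------------------------------------------------
# scaled RK4 kernel (numba-accelerated when available)
# ---------------------------------------------------------------------------


def _deriv(c, s, u, gc, gs, N, M_C, alpha, r, beta, gamma, eps):
    kappa = s / (gamma * c + s + eps)
    E = 1.0 - math.exp(-beta * u)
    ratio = s / (c + eps)
    eru = math.exp(r * u)
    F = gc * kappa * E * (1.0 - c) - alpha * eru * ratio - M_C
    dc = F * c
    ds = gs * (1.0 - ratio) * s
    du = N * (gc * kappa * (1.0 - c) * beta * math.exp(-beta * u) - alpha * r * eru * ratio)
    return dc, ds, du


def _step_months(c, s, u, gC, gS, mult, nsub, N, M_C, alpha, r, beta, gamma, eps,
                 out_c, out_s, out_u):
    """Integrate month-by-month with RK4; returns worst negative excursion.

    ``mult[m]`` is the bleaching retained fraction applied to s at the
    start of month m; end-of-month states are written to the out arrays.
    """
    h = 1.0 / nsub
    worst = 0.0
    for m in range(gC.shape[0]):
        s = s * mult[m]
        gc = gC[m]
        gs = gS[m]
        for _ in range(nsub):
            k1c, k1s, k1u = _deriv(c, s, u, gc, gs, N, M_C, alpha, r, beta, gamma, eps)
            c2 = c + 0.5 * h * k1c
            s2 = s + 0.5 * h * k1s
            u2 = u + 0.5 * h * k1u
            k2c, k2s, k2u = _deriv(c2, s2, u2, gc, gs, N, M_C, alpha, r, beta, gamma, eps)
            c3 = c + 0.5 * h * k2c
            s3 = s + 0.5 * h * k2s
            u3 = u + 0.5 * h * k2u
            k3c, k3s, k3u = _deriv(c3, s3, u3, gc, gs, N, M_C, alpha, r, beta, gamma, eps)
            c4 = c + h * k3c
            s4 = s + h * k3s
            u4 = u + h * k3u
            k4c, k4s, k4u = _deriv(c4, s4, u4, gc, gs, N, M_C, alpha, r, beta, gamma, eps)
            c = c + h / 6.0 * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
            s = s + h / 6.0 * (k1s + 2.0 * k2s + 2.0 * k3s + k4s)
            u = u + h / 6.0 * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
            if c < 0.0:
                if c < worst:
                    worst = c
                c = 0.0
            if s < 0.0:
                if s < worst:
                    worst = s
                s = 0.0
            if u < 0.0:
                if u < worst:
                    worst = u
                u = 0.0
        out_c[m] = c
        out_s[m] = s
        out_u[m] = u
    return worst


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _deriv = njit(cache=False)(_deriv)
    _step_months = njit(cache=False)(_step_months)
except ImportError:  # pragma: no cover
    logger.info("numba unavailable; using the pure-Python integrator loop")


def _integrate(
    y0: tuple[float, float, float],
    gC: np.ndarray,
    gS: np.ndarray,
    mult: np.ndarray,
    region: RegionParams,
    params: GlobalParams,
    settings: RunSettings,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the scaled system over len(gC) months from scaled state y0."""
    n = gC.shape[0]
    out_c = np.empty(n)
    out_s = np.empty(n)
    out_u = np.empty(n)
    gamma = params.Gamma_h / params.K_smax
    eps = settings.epsilon_guard
    if settings.integrator == "rk4":
        worst = _step_months(
            float(y0[0]), float(y0[1]), float(y0[2]),
            np.ascontiguousarray(gC, dtype=float),
            np.ascontiguousarray(gS, dtype=float),
            np.ascontiguousarray(mult, dtype=float),
            settings.substeps_per_month,
            region.N, params.M_C, params.alpha, params.r, params.beta, gamma, eps,
            out_c, out_s, out_u,
        )
        if worst < 0.0:
            if worst < -settings.clip_tol:
                raise FloatingPointError(
                    f"negative excursion {worst:.3e} (scaled) exceeds clip "
                    f"tolerance {settings.clip_tol:.1e}"
                )
            logger.warning("clipped negative excursion of %.3e (scaled) to zero", worst)
    else:
        from scipy.integrate import solve_ivp

        def fun(t, y, gc, gs):
            return _deriv(
                y[0], y[1], y[2], gc, gs,
                region.N, params.M_C, params.alpha, params.r, params.beta, gamma, eps,
            )

        c, s, u = map(float, y0)
        for m in range(n):
            s *= mult[m]
            sol = solve_ivp(
                fun, (0.0, 1.0), (c, s, u), args=(float(gC[m]), float(gS[m])),
                method="LSODA", rtol=1e-10, atol=1e-35,
            )
            if not sol.success:
                raise FloatingPointError(f"adaptive integrator failed in month {m}: {sol.message}")
            c, s, u = (max(v, 0.0) for v in sol.y[:, -1])
            out_c[m], out_s[m], out_u[m] = c, s, u
    if not (np.all(np.isfinite(out_c)) and np.all(np.isfinite(out_s)) and np.all(np.isfinite(out_u))):
        bad = int(np.argmax(~(np.isfinite(out_c) & np.isfinite(out_s) & np.isfinite(out_u))))
        raise FloatingPointError(f"non-finite state at month {bad}")
    return out_c, out_s, out_u


def scaled_rhs_norm(
    state: ModelState,
    T: float,
    region: RegionParams,
    params: GlobalParams = GlobalParams(),
    eps: float = 1e-12,
) -> float:
    """Max-abs norm of the scaled right-hand side at a state (month^-1)."""
    gamma = params.Gamma_h / params.K_smax
    scale = params.K_smax * region.K_C
    d = _deriv(
        state.C / region.K_C, state.S / scale, state.U,
        float(core.coral_growth_rate(T, region, params)),
        float(core.symbiont_growth_rate(T, params)),
        region.N, params.M_C, params.alpha, params.r, params.beta, gamma, eps,
    )
    return float(max(abs(v) for v in d))


def spin_up(
    region: RegionParams,
    params: GlobalParams = GlobalParams(),
    settings: RunSettings | None = None,
    *,
    years: int = SPINUP_YEARS,
    C0: float | None = None,
    S0: float = DEFAULT_INITIAL_CONDITIONS["S"],
    U0: float = DEFAULT_INITIAL_CONDITIONS["U"],
    equilibrium_tol: float = 1e-8,
) -> ModelState:
    """Run the fixed-temperature spin-up phase and return the final state.

    Integrates ``years`` (default 2000) of months at the region's fixed
    spin-up temperature with bleaching off, starting from the published
    initial conditions C = 0.75*K_C, S = 1e-3 cells, U = 5e-7.  Warns if
    the scaled derivative norm at the end exceeds ``equilibrium_tol``
    (the slow trait dynamics may still be drifting).
    """
    settings = settings or RunSettings()
    if C0 is None:
        C0 = DEFAULT_INITIAL_CONDITIONS["C_frac"] * region.K_C
    n = years * 12
    scale = params.K_smax * region.K_C
    gC = np.full(n, float(core.coral_growth_rate(region.spinup_T, region, params)))
    gS = np.full(n, float(core.symbiont_growth_rate(region.spinup_T, params)))
    mult = np.ones(n)
    y0 = (C0 / region.K_C, S0 / scale, U0)
    out_c, out_s, out_u = _integrate(y0, gC, gS, mult, region, params, settings)
    state = ModelState(
        C=float(out_c[-1] * region.K_C),
        S=float(out_s[-1] * scale),
        U=float(out_u[-1]),
        t=0.0,
    )
    norm = scaled_rhs_norm(state, region.spinup_T, region, params, settings.epsilon_guard)
    if norm > equilibrium_tol:
        warnings.warn(
            f"spin-up for {region.name or 'region'} ended with scaled derivative "
            f"norm {norm:.2e} month^-1 (> {equilibrium_tol:.0e}): state still "
            "drifting on the slow acclimation manifold",
            RuntimeWarning,
            stacklevel=2,
        )
    return state


def run(
    state0: ModelState,
    forcing: TemperatureSeries,
    region: RegionParams,
    params: GlobalParams = GlobalParams(),
    settings: RunSettings | None = None,
) -> Trajectory:
    """Integrate the model through a monthly forcing record.

    For each month the bleaching condition is evaluated first (when
    enabled): if the month's temperature exceeds T_opt by a margin inside
    one of the region's bands, S is instantaneously reduced by a uniform
    draw from the band's reduction range.  The ODEs are then integrated
    across the month with that month's temperature held constant.
    """
    settings = settings or RunSettings()
    n = len(forcing)
    scale = params.K_smax * region.K_C
    gC = np.asarray(core.coral_growth_rate(forcing.values, region, params), dtype=float)
    gS = np.asarray(core.symbiont_growth_rate(forcing.values, params), dtype=float)
    if settings.bleaching_enabled:
        rng = np.random.default_rng(settings.seed)
        mult, stubs = draw_monthly_reductions(
            forcing.values, region.T_opt, region.bleaching_bands, rng
        )
    else:
        mult, stubs = np.ones(n), []
    y0 = (state0.C / region.K_C, state0.S / scale, state0.U)
    out_c, out_s, out_u = _integrate(y0, gC, gS, mult, region, params, settings)
    C_series = np.concatenate([[state0.C], out_c * region.K_C])
    S_series = np.concatenate([[state0.S], out_s * scale])
    U_series = np.concatenate([[state0.U], out_u])
    events = []
    for m, exceed, band_idx, rho in stubs:
        S_before = float(S_series[m])
        events.append(
            BleachingEvent(
                time=m,
                exceedance=exceed,
                band_index=band_idx,
                reduction_drawn=rho,
                S_before=S_before,
                S_after=(1.0 - rho / 100.0) * S_before,
            )
        )
    return Trajectory(
        start=forcing.start,
        T=forcing.values.copy(),
        C_series=C_series,
        S_series=S_series,
        U_series=U_series,
        events=tuple(events),
        region=region.name,
    )


def relative_abundance(traj: Trajectory, region: RegionParams) -> np.ndarray:
    """Coral cover as percent of the regional carrying capacity."""
    return 100.0 * traj.C_series / region.K_C


def _window_mean(traj: Trajectory, series: np.ndarray, years: tuple[int, int]) -> float:
    """Mean of end-of-month samples over a closed calendar-year window."""
    y0, y1 = years
    sample_years = traj.sample_years()
    sel = (sample_years >= y0) & (sample_years <= y1)
    expected = (y1 - y0 + 1) * 12
    if sel.sum() != expected:
        raise ValueError(
            f"trajectory ({traj.start}..) does not fully cover years {y0}-{y1}"
        )
    return float(series[1:][sel].mean())


def decline_metric(
    traj: Trajectory,
    base: tuple[int, int] = (1986, 2005),
    fut: tuple[int, int] = (2081, 2100),
) -> float:
    """Percent decline of mean coral abundance, future vs baseline window.

    100*(1 - mean(C over fut)/mean(C over base)); negative means increase.
    """
    mb = _window_mean(traj, traj.C_series, base)
    mf = _window_mean(traj, traj.C_series, fut)
    return 100.0 * (1.0 - mf / mb)


def trait_change_metric(
    traj: Trajectory,
    base: tuple[int, int] = (1986, 2005),
    fut: tuple[int, int] = (2081, 2100),
) -> float:
    """Percent change of the mean energy-investment trait, future vs baseline."""
    mb = _window_mean(traj, traj.U_series, base)
    mf = _window_mean(traj, traj.U_series, fut)
    return 100.0 * (mf / mb - 1.0)
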