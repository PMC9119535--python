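"""One-at-a-time parameter sensitivity across speeds of acclimation.

Each scan perturbs a single model parameter by fixed factors (default
-25 %, baseline, +25 %), reruns the full protocol (spin-up plus forced
run) over a grid of acclimation speeds N, and records the time-mean coral
abundance — with or without the stochastic bleaching process (replicate-
averaged when on).  Row-wise max-scaling turns the absolute abundances
into the relative profiles used to display the headline robustness
result: mean coral abundance increases with the speed of acclimation
regardless of the perturbation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import _replicate_seeds, log_grid
from .forcing import TemperatureSeries
from .params import GlobalParams, RegionParams
from .simulate import RunSettings, run, spin_up

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityResult",
    "scan",
    "scale_abundance",
    "perturbable_parameters",
    "default_scan_parameters",
]

_REGION_SCALARS = ("K_C", "T_bar", "T_opt", "sigma", "skew_s", "spinup_T")


def perturbable_parameters() -> list[str]:
    """All scalar parameters a scan may perturb (N itself excluded)."""
    return [f.name for f in fields(GlobalParams)] + list(_REGION_SCALARS)


def default_scan_parameters() -> list[str]:
    """Parameters scanned by default: all physiological constants plus the
    region's capacity and thermal-curve shape.

    Temperatures (T_bar, T_opt, spinup_T) are excluded from the default
    set because a percentage of a Celsius reading is not scale-free; they
    can still be requested explicitly.
    """
    return [f.name for f in fields(GlobalParams)] + ["K_C", "sigma", "skew_s"]


@dataclass(frozen=True)
class SensitivityResult:
    """Mean-abundance matrix of one parameter scan (factors x N grid)."""

    parameter: str
    factors: tuple[float, ...]
    N_grid: tuple[float, ...]
    mean_abundance: np.ndarray  # shape (len(factors), len(N_grid)), cm^2
    bleaching_enabled: bool
    scaled: np.ndarray | None = None  # row-wise max-normalised copy

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_abundance, dtype=float)
        object.__setattr__(self, "mean_abundance", m)
        if m.shape != (len(self.factors), len(self.N_grid)):
            raise ValueError("mean_abundance shape must be (factors, N_grid)")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: parameter, factor, N, mean_abundance, scaled."""
        rows = []
        for i, f in enumerate(self.factors):
            for j, n in enumerate(self.N_grid):
                rows.append(
                    {
                        "parameter": self.parameter,
                        "factor": f,
                        "N": n,
                        "mean_abundance": self.mean_abundance[i, j],
                        "scaled": None if self.scaled is None else self.scaled[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _perturbed(
    parameter: str, factor: float, region: RegionParams, params: GlobalParams
) -> tuple[RegionParams, GlobalParams]:
    if parameter in {f.name for f in fields(GlobalParams)}:
        return region, replace(params, **{parameter: getattr(params, parameter) * factor})
    if parameter in _REGION_SCALARS:
        return region.perturb(parameter, factor), params
    raise ValueError(
        f"unknown parameter {parameter!r}; valid names: {perturbable_parameters()}"
    )


def scan(
    parameter: str,
    region: RegionParams,
    params: GlobalParams,
    forcing: TemperatureSeries,
    N_grid: Sequence[float] | None = None,
    factors: Sequence[float] = (0.75, 1.0, 1.25),
    settings: RunSettings | None = None,
    replicates: int = 10,
) -> SensitivityResult:
    """Perturb one parameter and measure mean coral abundance over (factor, N).

    For every factor the parameter is multiplied on a copy (inputs are
    never mutated); for every candidate N the protocol runs spin-up plus
    the forced era, and the time-mean coral abundance over the whole run
    is recorded, averaged over bleaching replicates when bleaching is on.
    Bleaching seeds are shared across (factor, N) cells so the factor-1
    row reproduces the unperturbed baseline exactly.
    """
    settings = settings or RunSettings()
    if N_grid is None:
        N_grid = log_grid()
    reps = replicates if settings.bleaching_enabled else 1
    seeds = _replicate_seeds(settings, reps)
    matrix = np.empty((len(factors), len(N_grid)))
    for i, factor in enumerate(factors):
        reg_f, par_f = _perturbed(parameter, float(factor), region, params)
        for j, N in enumerate(N_grid):
            reg = replace(reg_f, N=float(N))
            state0 = spin_up(reg, par_f, settings, equilibrium_tol=np.inf)
            acc = 0.0
            for seed in seeds:
                traj = run(state0, forcing, reg, par_f, replace(settings, seed=int(seed)))
                acc += float(traj.C_series[1:].mean())
            matrix[i, j] = acc / reps
    return SensitivityResult(
        parameter=parameter,
        factors=tuple(float(f) for f in factors),
        N_grid=tuple(float(n) for n in N_grid),
        mean_abundance=matrix,
        bleaching_enabled=settings.bleaching_enabled,
    )


def scale_abundance(result: SensitivityResult) -> SensitivityResult:
    """Row-wise max-normalisation of the abundance matrix.

    Each factor row is divided by its own maximum, making the increase of
    abundance with N directly comparable across perturbations; an all-zero
    row stays zero (logged).
    """
    m = result.mean_abundance
    scaled = np.zeros_like(m)
    for i in range(m.shape[0]):
        mx = m[i].max()
        if mx > 0:
            scaled[i] = m[i] / mx
        else:
            logger.warning(
                "scale_abundance: all-zero row for %s factor %g",
                result.parameter,
                result.factors[i],
            )
    return replace(result, scaled=scaled)
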