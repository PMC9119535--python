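"""Statsmodels-style front end: a model object fitted to cover data.

:class:`CoralAcclimationModel` bundles the observational inputs (yearly
percent-cover observations and the monthly SST forcing of one region)
with the model configuration; :meth:`~CoralAcclimationModel.fit` estimates
the speed of acclimation N by grid search and returns a
:class:`CoralAcclimationResults` carrying the estimate, the loss curve,
fitted yearly covers and diagnostics, with ``summary()``, ``simulate()``
and ``plot_fit()`` attached.

Example
-------
>>> model = CoralAcclimationModel(observations, forcing, region="GBR")
>>> res = model.fit()
>>> print(res.summary())
>>> proj = res.simulate(scenario_forcing)   # Trajectory at the fitted N
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibrate as _cal
from .calibrate import CalibrationResult, CoverObservation
from .forcing import TemperatureSeries
from .params import GlobalParams, RegionParams, region_preset
from .simulate import RunSettings, Trajectory, run, spin_up

__all__ = ["CoralAcclimationModel", "CoralAcclimationResults"]


def _as_observations(obs, region_name: str) -> list[CoverObservation]:
    if isinstance(obs, pd.DataFrame):
        return [
            CoverObservation(int(r.year), float(r.cover_pct), region_name)
            for r in obs.itertuples()
        ]
    out = list(obs)
    if not all(isinstance(o, CoverObservation) for o in out):
        raise TypeError(
            "observations must be CoverObservation items or a DataFrame "
            "with columns year, cover_pct"
        )
    return out


class CoralAcclimationModel:
    """Coral-cover acclimation model for one region.

    Parameters
    ----------
    observations
        Yearly percent-cover observations: a sequence of
        :class:`CoverObservation` or a DataFrame with ``year`` and
        ``cover_pct`` columns.  Multiple observations per year are
        reduced to the yearly median.
    forcing
        Monthly SST record covering the observation years.
    region
        Region preset name ('GBR', 'SEA', 'CAR') or a RegionParams.
    params, settings
        Physiological constants and numerical settings (defaults used
        when omitted).
    """

    def __init__(
        self,
        observations,
        forcing: TemperatureSeries,
        region: str | RegionParams = "GBR",
        params: GlobalParams | None = None,
        settings: RunSettings | None = None,
    ) -> None:
        self.region = region_preset(region) if isinstance(region, str) else region
        self.observations = _as_observations(observations, self.region.name)
        self.forcing = forcing
        self.params = params or GlobalParams()
        self.settings = settings or RunSettings()
        self.obs_medians: dict[int, float] = _cal.yearly_median(self.observations)
        missing = [y for y in self.obs_medians if y not in set(forcing.years)]
        if missing:
            raise ValueError(f"forcing does not cover observation year(s) {missing}")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, forcing: TemperatureSeries, **kwargs
    ) -> "CoralAcclimationModel":
        """Construct from a DataFrame with ``year`` and ``cover_pct`` columns."""
        return cls(df, forcing, **kwargs)

    def fit(
        self,
        grid: Sequence[float] | None = None,
        replicates: int = 10,
    ) -> "CoralAcclimationResults":
        """Estimate N by least squares on yearly medians over a log grid."""
        grid = _cal.log_grid() if grid is None else np.asarray(grid, dtype=float)
        covers = _cal.simulate_candidate_covers(
            grid, self.forcing, list(self.obs_medians), self.region,
            self.params, self.settings, replicates,
        )
        N_star, curve = _cal.loss_from_covers(covers, self.obs_medians)
        calib = CalibrationResult(
            N_star=N_star,
            loss_curve=curve,
            region=self.region.name,
            replicates=replicates,
            settings=self.settings,
        )
        return CoralAcclimationResults(self, calib, covers)


class CoralAcclimationResults:
    """Fit results: the estimated speed of acclimation and diagnostics."""

    def __init__(
        self,
        model: CoralAcclimationModel,
        calibration: CalibrationResult,
        candidate_covers: pd.DataFrame,
    ) -> None:
        self.model = model
        self.calibration = calibration
        self.candidate_covers = candidate_covers
        self.N_star = calibration.N_star
        #: fitted yearly cover at the selected N (percent of carrying capacity)
        self.fittedvalues = candidate_covers[self.N_star]
        obs = pd.Series(model.obs_medians, dtype=float)
        self.resid = obs - self.fittedvalues.reindex(obs.index)

    @property
    def params(self) -> dict[str, float]:
        return {"N": self.N_star}

    @property
    def loss_curve(self) -> tuple[tuple[float, float], ...]:
        return self.calibration.loss_curve

    def grid_uncertainty(self) -> tuple[float, float]:
        """Bracketing grid neighbours of the estimate (grid-resolution bound)."""
        grid = self.calibration.grid
        i = int(np.argmin(np.abs(grid - self.N_star)))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        return float(lo), float(hi)

    def region_at_fit(self) -> RegionParams:
        """Region parameters with N replaced by the estimate."""
        return replace(self.model.region, N=self.N_star)

    def simulate(
        self,
        forcing: TemperatureSeries | None = None,
        settings: RunSettings | None = None,
    ) -> Trajectory:
        """Full protocol (spin-up + forced run) at the fitted N."""
        reg = self.region_at_fit()
        settings = settings or self.model.settings
        state0 = spin_up(reg, self.model.params, settings, equilibrium_tol=np.inf)
        return run(state0, forcing or self.model.forcing, reg, self.model.params, settings)

    def summary(self) -> str:
        lo, hi = self.grid_uncertainty()
        rmse = float(np.sqrt(np.mean(self.resid.dropna() ** 2)))
        lines = [
            "Coral acclimation model - speed of acclimation fit",
            "=" * 52,
            f"Region:                 {self.calibration.region}",
            f"Observation years:      {min(self.model.obs_medians)}-{max(self.model.obs_medians)}"
            f" ({len(self.model.obs_medians)} yearly medians)",
            f"Candidate grid:         {len(self.calibration.grid)} points,"
            f" [{self.calibration.grid.min():.3g}, {self.calibration.grid.max():.3g}]",
            f"Bleaching replicates:   {self.calibration.replicates}",
            f"N (speed of acclim.):   {self.N_star:.4g} (energy cm^-2 month^-1)^2",
            f"Grid neighbours:        [{lo:.4g}, {hi:.4g}]",
            f"RMSE (yearly cover):    {rmse:.3f} percentage points",
            "=" * 52,
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed yearly medians vs fitted yearly cover and the loss curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs = pd.Series(self.model.obs_medians, dtype=float)
        ax.plot(obs.index, obs.values, "o", color="seagreen", label="observed median")
        ax.plot(
            self.fittedvalues.index,
            self.fittedvalues.values,
            color="purple",
            label=f"model, N={self.N_star:.3g}",
        )
        ax.set_xlabel("year")
        ax.set_ylabel("coral cover (% of carrying capacity)")
        ax.set_title(f"{self.calibration.region}: speed-of-acclimation fit")
        ax.legend()
        return ax
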