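"""Model parameters: cross-region physiological constants and region presets.

All values are the published literature/estimated constants for the
coral-algae acclimation model.  Containers are frozen dataclasses: a run
never mutates its parameters, and perturbation studies work on copies
(``dataclasses.replace`` or :meth:`RegionParams.perturb`).

Units
-----
Rates are per month; abundances are cm^2 of coral (C) and symbiont cells
(S); the energy-investment trait U carries the abstract unit
energy cm^-2 month^-1 (the model treats it as opaque), so ``r`` and
``beta`` are inverse trait units and the speed of acclimation ``N`` is a
squared trait unit.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path
from typing import Sequence

import yaml

from .bleaching import REGION_BANDS, BleachingBand, validate_bands

__all__ = [
    "GlobalParams",
    "RegionParams",
    "ModelState",
    "Derivatives",
    "REGIONS",
    "region_preset",
    "load_params",
    "dump_params",
]


@dataclass(frozen=True)
class GlobalParams:
    """Physiological constants shared by all regions.

    G_max : maximum coral growth rate, month^-1 (10 yr^-1 for a mixed
        massive/branching community)
    a, b : symbiont thermal growth envelope G_S(T) = a*exp(b*T)
    K_smax : symbiont carrying capacity per unit coral area, cells cm^-2
    M_C : background coral mortality, month^-1
    alpha, r : symbiotic cost mu = alpha*exp(r*U)*S/K_S
    beta : saturation rate of the energy-investment benefit E = 1-exp(-beta*U)
    Gamma_h : symbiont:host ratio at which the feedback kappa half-saturates
    """

    G_max: float = 0.83
    a: float = 0.09
    b: float = 0.063
    K_smax: float = 3e6
    M_C: float = 0.83e-3
    alpha: float = 1e-3
    r: float = 12e3
    beta: float = 12e2
    Gamma_h: float = 1e6

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"GlobalParams.{f.name} must be a positive finite number, got {v!r}")


@dataclass(frozen=True)
class RegionParams:
    """One region's thermal curve, capacity, bleaching and acclimation parameters.

    The thermal performance curve is a skew-normal density with location
    ``T_bar``, scale ``sigma`` and shape ``skew_s`` (treated as a
    dimensionless shape; the growth optimum T_opt is its mode).  ``N`` is
    the speed of acclimation, the constant linking trait change to the
    fitness gradient.  ``spinup_T`` is the fixed temperature used during
    the 2000-year spin-up (the regional 1955-2000 mean).
    """

    name: str
    K_C: float
    T_bar: float
    T_opt: float
    sigma: float
    skew_s: float
    N: float
    spinup_T: float
    bleaching_bands: tuple[BleachingBand, ...]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.K_C <= 0:
            raise ValueError("K_C must be > 0")
        if self.N < 0:
            raise ValueError("N must be >= 0")
        object.__setattr__(self, "bleaching_bands", tuple(self.bleaching_bands))
        validate_bands(self.bleaching_bands)

    def perturb(self, parameter: str, factor: float) -> "RegionParams":
        """Copy with one scalar field multiplied by ``factor``."""
        if parameter not in {f.name for f in fields(self)} or parameter in (
            "name",
            "bleaching_bands",
        ):
            raise ValueError(f"not a perturbable region parameter: {parameter}")
        return replace(self, **{parameter: getattr(self, parameter) * factor})


@dataclass(frozen=True)
class ModelState:
    """State (C, S, U) at time t (months since the simulation origin)."""

    C: float
    S: float
    U: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.C < 0 or self.S < 0 or self.U < 0:
            raise ValueError("state variables must be non-negative")


@dataclass(frozen=True)
class Derivatives:
    """Right-hand-side values (dC/dt, dS/dt, dU/dt) in natural units."""

    dC_dt: float
    dS_dt: float
    dU_dt: float


REGIONS: dict[str, RegionParams] = {
    "GBR": RegionParams(
        name="GBR",
        K_C=4.4e15,
        T_bar=26.8,
        T_opt=26.8,
        sigma=1.0,
        skew_s=2e-4,
        N=5.54e-13,
        spinup_T=25.90,
        bleaching_bands=REGION_BANDS["GBR"],
    ),
    "SEA": RegionParams(
        name="SEA",
        K_C=1.2e16,
        T_bar=28.1,
        T_opt=28.5,
        sigma=0.8,
        skew_s=3.8,
        N=2.65e-13,
        spinup_T=28.45,
        bleaching_bands=REGION_BANDS["SEA"],
    ),
    "CAR": RegionParams(
        name="CAR",
        K_C=1.9e15,
        T_bar=27.1,
        T_opt=27.6,
        sigma=0.9,
        skew_s=1.1,
        N=2.375e-13,
        spinup_T=27.57,
        bleaching_bands=REGION_BANDS["CAR"],
    ),
}


def region_preset(name: str) -> RegionParams:
    """Published preset for 'GBR', 'SEA' or 'CAR'."""
    try:
        return REGIONS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown region {name!r}; presets: {sorted(REGIONS)}"
        ) from None


# ---------------------------------------------------------------------------
# config serialization: keys follow the published symbol names
# ---------------------------------------------------------------------------

_GLOBAL_KEYS = ("G_max", "a", "b", "K_smax", "M_C", "alpha", "r", "beta", "Gamma_h")
_REGION_KEYS = ("K_C", "T_bar", "T_opt", "sigma", "s", "N", "spinup_T")


def params_to_dict(region: RegionParams, glob: GlobalParams) -> dict:
    """Serialize to a plain dict with the published symbol names as keys."""
    d: dict = {k: getattr(glob, k) for k in _GLOBAL_KEYS}
    d.update(
        name=region.name,
        K_C=region.K_C,
        T_bar=region.T_bar,
        T_opt=region.T_opt,
        sigma=region.sigma,
        s=region.skew_s,
        N=region.N,
        spinup_T=region.spinup_T,
        bleaching_bands=[
            {
                "exceedance_low": b.exceedance_low,
                "exceedance_high": (
                    None if math.isinf(b.exceedance_high) else b.exceedance_high
                ),
                "reduction_low": b.reduction_low,
                "reduction_high": b.reduction_high,
            }
            for b in region.bleaching_bands
        ],
    )
    return d


def params_from_dict(d: dict) -> tuple[RegionParams, GlobalParams]:
    """Inverse of :func:`params_to_dict`; missing keys fall back to defaults.

    A ``name`` matching a preset supplies regional defaults, so a minimal
    config like ``{name: GBR}`` resolves to the full published parameter set.
    """
    known = set(_GLOBAL_KEYS) | set(_REGION_KEYS) | {"name", "bleaching_bands"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
    glob = GlobalParams(**{k: float(d[k]) for k in _GLOBAL_KEYS if k in d})
    name = d.get("name", "GBR")
    base = REGIONS.get(str(name).upper())
    if "bleaching_bands" in d:
        bands = tuple(
            BleachingBand(
                float(b["exceedance_low"]),
                math.inf if b.get("exceedance_high") is None else float(b["exceedance_high"]),
                float(b["reduction_low"]),
                float(b["reduction_high"]),
            )
            for b in d["bleaching_bands"]
        )
    elif base is not None:
        bands = base.bleaching_bands
    else:
        raise ValueError(f"bleaching_bands required for non-preset region {name!r}")
    def pick(key: str, attr: str):
        if key in d:
            return float(d[key])
        if base is None:
            raise ValueError(f"parameter {key!r} required for non-preset region {name!r}")
        return getattr(base, attr)

    region = RegionParams(
        name=str(name),
        K_C=pick("K_C", "K_C"),
        T_bar=pick("T_bar", "T_bar"),
        T_opt=pick("T_opt", "T_opt"),
        sigma=pick("sigma", "sigma"),
        skew_s=pick("s", "skew_s"),
        N=pick("N", "N"),
        spinup_T=pick("spinup_T", "spinup_T"),
        bleaching_bands=bands,
    )
    return region, glob


def dump_params(region: RegionParams, glob: GlobalParams, path) -> None:
    """Write parameters to YAML or JSON (by file extension)."""
    d = params_to_dict(region, glob)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_params(path) -> tuple[RegionParams, GlobalParams]:
    """Read parameters from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return params_from_dict(d)
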