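"""Thin-layer drying kinetics for a spherical product.

The moisture ratio MR(t) of a sphere drying in the falling-rate period
follows Fick's second law of diffusion; its series solution is

    MR(t) = (6/pi^2) * sum_{n>=1} (1/n^2) exp(-n^2 pi^2 Deff t / r^2)

so at long times ln MR is linear in t with slope K_L = -pi^2 Deff / r^2.
This module implements the slope method for the effective moisture
diffusivity Deff, the Arrhenius regression for the activation energy Ea,
and the total/specific energy accounting of a convective dryer.

Two unit conventions for Deff are supported.  ``mode="table"`` applies the
per-minute regression slope with no time-unit conversion, which is the
convention under which the source tables of this analysis are internally
consistent; ``mode="si"`` divides by 60 to express Deff in m^2/s.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateCurveError,
    InsufficientDataError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

#: Universal gas constant, J/(mol K).
GAS_CONSTANT = 8.314
#: Celsius -> kelvin offset.
KELVIN_OFFSET = 273.15
#: Characteristic fruit radius, m (whole fruit ~0.020 m long).
DEFAULT_RADIUS_M = 0.02
#: Amplitude of the one-term sphere solution, 6/pi^2 ~ 0.6079.  Points with
#: MR above this value cannot satisfy the one-term form for any Deff.
SINGLE_TERM_AMPLITUDE = 6.0 / np.pi**2
#: Default upper cutoff of the late-time slope fit: (6/pi^2) e^-1 ~ 0.2236,
#: one diffusive time constant into the decay.  There the second series
#: term is below (1/4) e^-3 ~ 1.2% of the first, so the one-term slope is
#: essentially unbiased.
LATE_TIME_MR = SINGLE_TERM_AMPLITUDE * float(np.exp(-1))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """Ordinary least-squares line y = slope*x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InvalidInputError("a line fit needs at least 2 points")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise InvalidInputError(f"R^2 out of [0, 1]: {self.r_squared}")


@dataclass
class MoistureState:
    """Moisture bookkeeping for one sample (dry-basis convention)."""

    wet_weight_g: float
    dry_weight_g: float
    moisture_content_db_pct: float
    mt: float = 0.0   # instantaneous moisture, g water / g dry matter
    mo: float = 0.0   # initial moisture
    me: float = 0.0   # equilibrium moisture

    def __post_init__(self) -> None:
        if self.dry_weight_g <= 0:
            raise InvalidInputError("dry weight must be positive")
        if self.mo < self.me:
            raise InvalidInputError("initial moisture below equilibrium moisture")


@dataclass
class DryingCurve:
    """One pretreatment x temperature drying cell.

    ``times`` are elapsed minutes, strictly increasing from 0;
    ``moisture_ratios`` is the dimensionless MR series.  Values outside
    [-mr_tolerance, 1 + mr_tolerance] and a first MR away from 1 are
    flagged and logged, not rejected: measured curves can overshoot.
    """

    pretreatment_min: float
    temperature_C: float
    times: np.ndarray
    moisture_ratios: np.ndarray
    radius_m: float = DEFAULT_RADIUS_M
    initial_mass_kg: float = 0.2
    mr_tolerance: float = 0.02
    out_of_range: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.moisture_ratios = np.asarray(self.moisture_ratios, dtype=float)
        if self.times.shape != self.moisture_ratios.shape or self.times.ndim != 1:
            raise InvalidInputError("times and moisture_ratios must be equal-length 1-D")
        if self.times.size == 0:
            raise InvalidInputError("empty drying curve")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.times[0] != 0:
            raise InvalidInputError("drying curve must start at t = 0")
        if self.radius_m <= 0:
            raise InvalidInputError("radius must be positive")
        eps = self.mr_tolerance
        self.out_of_range = (self.moisture_ratios < -eps) | (self.moisture_ratios > 1 + eps)
        if self.out_of_range.any():
            logger.warning(
                "curve (%s min, %s C): %d moisture ratios outside [%g, %g]",
                self.pretreatment_min, self.temperature_C,
                int(self.out_of_range.sum()), -eps, 1 + eps,
            )
        if abs(self.moisture_ratios[0] - 1.0) > eps:
            logger.warning(
                "curve (%s min, %s C): first MR %.4f differs from 1",
                self.pretreatment_min, self.temperature_C, self.moisture_ratios[0],
            )


@dataclass
class DiffusivityResult:
    """Slope-method effective moisture diffusivity."""

    deff: float
    fit: LinearFit
    mode: str
    physical: bool = True


@dataclass
class ArrheniusResult:
    """Arrhenius fit of ln Deff against 1/T."""

    ea_kj_per_mol: float
    d0: float
    fit: LinearFit


@dataclass
class EnergyResult:
    """Total and specific drying-energy consumption."""

    et_kwh: float
    es_kwh_per_kg: float
    inputs: dict


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def moisture_content(wet_weight_g: float, dry_weight_g: float) -> float:
    """Dry-basis moisture content, percent: 100 * (Ww - Dw) / Dw."""
    if dry_weight_g <= 0:
        raise InvalidInputError(f"dry weight must be positive, got {dry_weight_g}")
    return 100.0 * (wet_weight_g - dry_weight_g) / dry_weight_g


def moisture_ratio(mt: float, mo: float, me: float = 0.0):
    """Dimensionless moisture ratio (Mt - Me) / (Mo - Me).

    Equals 1 at the start of drying and tends to 0 as the sample approaches
    its equilibrium moisture content Me (default 0, the standard thin-layer
    simplification when Me is not measured).
    """
    if mo <= me:
        raise DegenerateCurveError(
            f"initial moisture {mo} must exceed equilibrium moisture {me}"
        )
    return (np.asarray(mt) - me) / (mo - me) if np.ndim(mt) else (mt - me) / (mo - me)


def fit_ln_mr(curve: DryingCurve, min_mr: float = 0.01,
              max_mr: float | None = None) -> LinearFit:
    """OLS fit of ln MR against drying time (minutes).

    Points with MR <= max(min_mr, 0) are excluded (ln undefined at 0);
    an optional ``max_mr`` restricts the fit to the late-time window where
    the one-term sphere solution holds (see :data:`SINGLE_TERM_AMPLITUDE`).
    Excluded points are logged.
    """
    mr = curve.moisture_ratios
    keep = mr > max(min_mr, 0.0)
    if max_mr is not None:
        keep &= mr < max_mr
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("fit_ln_mr: excluding %d of %d points outside (%g, %s)",
                    n_dropped, mr.size, min_mr, max_mr)
    if int(keep.sum()) < 2:
        raise InsufficientDataError(
            f"only {int(keep.sum())} usable points (need >= 2) with MR in "
            f"({min_mr}, {max_mr})"
        )
    t, y = curve.times[keep], np.log(mr[keep])
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=min(r2, 1.0), n_points=int(keep.sum()))


def deff_from_slope(fit: LinearFit, radius_m: float = DEFAULT_RADIUS_M,
                    mode: str = "table") -> DiffusivityResult:
    """Effective moisture diffusivity from the ln-MR slope: |K_L| r^2 / pi^2.

    ``mode="table"`` keeps the per-minute slope unconverted (the convention
    of the reference tables); ``mode="si"`` divides by 60 for m^2/s.
    A non-negative slope is non-physical and yields Deff = 0 with a warning.
    """
    if mode not in ("table", "si"):
        raise InvalidInputError(f"mode must be 'table' or 'si', got {mode!r}")
    if radius_m <= 0:
        raise InvalidInputError("radius must be positive")
    if fit.slope >= 0:
        warnings.warn(
            f"non-negative ln-MR slope {fit.slope}: no drying signal; Deff set to 0",
            stacklevel=2,
        )
        return DiffusivityResult(deff=0.0, fit=fit, mode=mode, physical=False)
    deff = abs(fit.slope) * radius_m**2 / np.pi**2
    if mode == "si":
        deff /= 60.0
    logger.debug("deff_from_slope: slope=%g r=%g mode=%s -> %g", fit.slope,
                 radius_m, mode, deff)
    return DiffusivityResult(deff=float(deff), fit=fit, mode=mode)


def arrhenius_fit(deff_by_temp: Mapping[float, float] | Iterable[tuple[float, float]]
                  ) -> ArrheniusResult:
    """Activation energy from ln Deff regressed on 1/T (kelvin).

    Ea = -slope * R (reported in kJ/mol); D0 = exp(intercept), in the same
    units as the supplied diffusivities.  Ea is invariant to any constant
    rescaling of the Deff values.  Duplicate temperatures are averaged with
    a warning.
    """
    pairs = list(deff_by_temp.items()) if isinstance(deff_by_temp, Mapping) \
        else list(deff_by_temp)
    by_temp: dict[float, list[float]] = {}
    for temp_c, deff in pairs:
        by_temp.setdefault(float(temp_c), []).append(float(deff))
    if any(len(v) > 1 for v in by_temp.values()):
        warnings.warn("duplicate temperatures averaged in Arrhenius fit", stacklevel=2)
    temps = np.array(sorted(by_temp))
    deffs = np.array([np.mean(by_temp[t]) for t in temps])
    if temps.size < 2:
        raise InsufficientDataError("Arrhenius fit needs >= 2 distinct temperatures")
    if np.any(deffs <= 0):
        raise InvalidInputError("all diffusivities must be positive")
    inv_t = 1.0 / (temps + KELVIN_OFFSET)
    y = np.log(deffs)
    res = stats.linregress(inv_t, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
    fit = LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                    r_squared=min(r2, 1.0), n_points=temps.size)
    return ArrheniusResult(
        ea_kj_per_mol=-fit.slope * GAS_CONSTANT / 1000.0,
        d0=float(np.exp(fit.intercept)),
        fit=fit,
    )


def total_energy(area_m2: float, velocity_m_s: float, air_density: float,
                 specific_heat_kj: float, delta_t_c: float,
                 drying_time_h: float) -> float:
    """Total drying energy, kWh: A * v * rho_a * c_a * dT * Dt / 3600.

    The raw product (with c_a in kJ/(kg C) and Dt in hours) is treated as
    kJ and converted to kWh with the single factor 1/3600.
    """
    inputs = (area_m2, velocity_m_s, air_density, specific_heat_kj,
              delta_t_c, drying_time_h)
    if any(v < 0 for v in inputs):
        raise InvalidInputError(f"energy inputs must be non-negative: {inputs}")
    return float(np.prod(inputs)) / 3600.0


def specific_energy(et_kwh: float, initial_mass_kg: float) -> float:
    """Specific energy consumption, kWh per kg of initial product mass."""
    if initial_mass_kg <= 0:
        raise InvalidInputError("initial mass must be positive")
    return et_kwh / initial_mass_kg


def energy_result(area_m2: float, velocity_m_s: float, air_density: float,
                  specific_heat_kj: float, delta_t_c: float,
                  drying_time_h: float, initial_mass_kg: float) -> EnergyResult:
    """Convenience wrapper returning both total and specific energy."""
    et = total_energy(area_m2, velocity_m_s, air_density, specific_heat_kj,
                      delta_t_c, drying_time_h)
    return EnergyResult(
        et_kwh=et,
        es_kwh_per_kg=specific_energy(et, initial_mass_kg),
        inputs=dict(area_m2=area_m2, velocity_m_s=velocity_m_s,
                    air_density=air_density, specific_heat_kj=specific_heat_kj,
                    delta_t_c=delta_t_c, drying_time_h=drying_time_h,
                    initial_mass_kg=initial_mass_kg),
    )


# ---------------------------------------------------------------------------
# dataset-level pipeline
# ---------------------------------------------------------------------------

def curves_from_frame(df, radius_m: float = DEFAULT_RADIUS_M) -> list[DryingCurve]:
    """Split a long-format drying table into per-cell :class:`DryingCurve`."""
    curves = []
    for (pre, temp), grp in df.groupby(["pretreatment_min", "temperature_C"]):
        grp = grp.sort_values("time_min")
        curves.append(DryingCurve(
            pretreatment_min=float(pre), temperature_C=float(temp),
            times=grp["time_min"].to_numpy(dtype=float),
            moisture_ratios=grp["moisture_ratio"].to_numpy(dtype=float),
            radius_m=radius_m,
        ))
    return curves


def analyze_dataset(df, radius_m: float = DEFAULT_RADIUS_M, mode: str = "table",
                    min_mr: float = 0.01,
                    max_mr: float | None = LATE_TIME_MR):
    """Slope-method Deff per cell plus per-pretreatment Arrhenius fits.

    Defaults to the late-time fit window MR < (6/pi^2) e^-1, where the
    one-term sphere solution governs the decay; pass ``max_mr=None`` to
    regress over every positive point instead.

    Returns ``(deff_table, ea_table)`` as pandas DataFrames mirroring the
    diffusivity and activation-energy report layouts.
    """
    import pandas as pd

    logger.info("kinetics: r=%g m, mode=%s, fit window MR in (%g, %s)",
                radius_m, mode, min_mr, max_mr)
    rows = []
    for curve in curves_from_frame(df, radius_m=radius_m):
        fit = fit_ln_mr(curve, min_mr=min_mr, max_mr=max_mr)
        res = deff_from_slope(fit, radius_m=radius_m, mode=mode)
        rows.append(dict(
            pretreatment_min=curve.pretreatment_min,
            temperature_C=curve.temperature_C,
            deff=res.deff, slope=fit.slope, intercept=fit.intercept,
            r2=fit.r_squared, n_points=fit.n_points, physical=res.physical,
        ))
    deff_table = pd.DataFrame(rows).sort_values(
        ["pretreatment_min", "temperature_C"]).reset_index(drop=True)

    ea_rows = []
    for pre, grp in deff_table[deff_table["physical"]].groupby("pretreatment_min"):
        if grp["temperature_C"].nunique() < 2:
            logger.warning("pretreatment %s: <2 temperatures, skipping Arrhenius", pre)
            continue
        ar = arrhenius_fit(dict(zip(grp["temperature_C"], grp["deff"])))
        ea_rows.append(dict(pretreatment_min=pre, ea_kj_mol=ar.ea_kj_per_mol,
                            d0=ar.d0, r2=ar.fit.r_squared))
    ea_table = pd.DataFrame(ea_rows)
    return deff_table, ea_table
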