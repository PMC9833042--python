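"""Rubisco kinetic constants and their temperature responses.

This module holds the biochemical side of the package: containers for the
four Rubisco kinetic constants (carboxylation turnover rate ``kcat_co2``,
CO2/O2 specificity ``s_co``, and the Michaelis constants ``k_c`` and
``k_o``), evaluation and least-squares fitting of their Arrhenius
temperature responses, the derived photosynthetic quantities (the apparent
Michaelis constant at 21% O2 and the CO2 compensation point Γ*), and the
Henry-law unit bridge between dissolved-phase kinetics (µM) and gas-phase
mole fractions (µmol mol⁻¹).

The Arrhenius form used throughout is the Celsius parameterisation

    P(T) = P(25 °C) · exp[(T − 25)·Ea / (298·R·(273 + T))]

with ``Ea`` in kJ mol⁻¹ and ``R = 8.314`` J K⁻¹ mol⁻¹, so the constant at
25 °C is the anchor and the exponent vanishes exactly at 25 °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .exceptions import DomainError, FitError, InputError

__all__ = [
    "R_GAS",
    "T_REF",
    "TemperatureResponse",
    "RubiscoKinetics",
    "KineticConstants",
    "GasSolubility",
    "ArrheniusFit",
    "arrhenius_value",
    "fit_arrhenius",
    "kinetics_at_temperature",
    "kc_apparent_o2",
    "gamma_star_from_sco",
    "dissolved_concentration",
    "mole_fraction_from_dissolved",
    "derived_constants",
    "DerivedConstants",
    "default_solubility",
]

#: Universal gas constant, J K⁻¹ mol⁻¹.
R_GAS = 8.314

#: Reference temperature of the Arrhenius parameterisation, °C.
T_REF = 25.0

# Physically sane assay range for leaf/enzyme temperatures, °C.
_T_MIN, _T_MAX = -10.0, 60.0


@dataclass(frozen=True)
class TemperatureResponse:
    """One kinetic constant's value at 25 °C and its activation energy.

    Parameters
    ----------
    value_25:
        Parameter value at 25 °C, in the parameter's own units. Must be
        strictly positive (all four Rubisco constants are rates or
        concentrations).
    e_a:
        Activation energy in kJ mol⁻¹. May be negative: the specificity
        factor declines with temperature (apparent Ea ≈ −20 to −24 kJ mol⁻¹).
    se_25, se_ea:
        Optional standard errors (same units as the value / Ea).
    """

    value_25: float
    e_a: float
    se_25: float | None = None
    se_ea: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value_25) or self.value_25 <= 0.0:
            raise DomainError(f"value_25 must be positive, got {self.value_25!r}")
        if not math.isfinite(self.e_a):
            raise DomainError(f"e_a must be finite, got {self.e_a!r}")
        for name in ("se_25", "se_ea"):
            se = getattr(self, name)
            if se is not None and (not math.isfinite(se) or se < 0.0):
                raise DomainError(f"{name} must be non-negative, got {se!r}")


@dataclass(frozen=True)
class RubiscoKinetics:
    """The four Rubisco kinetic constants for one growth treatment.

    ``k_c`` and ``k_o`` are dissolved-phase Michaelis constants in µM,
    ``s_co`` is in M M⁻¹ and ``kcat_co2`` in s⁻¹ per catalytic site.
    """

    kcat_co2: TemperatureResponse
    s_co: TemperatureResponse
    k_c: TemperatureResponse
    k_o: TemperatureResponse
    label: str = ""

    def __post_init__(self) -> None:
        if self.k_o.value_25 <= self.k_c.value_25:
            raise DomainError(
                "k_o(25) must exceed k_c(25): O2 affinity of Rubisco is far "
                f"weaker than CO2 affinity (got {self.k_o.value_25} <= "
                f"{self.k_c.value_25})"
            )

    def at_temperature(self, t: float) -> "KineticConstants":
        return kinetics_at_temperature(self, t)


@dataclass(frozen=True)
class KineticConstants:
    """The four constants evaluated at a single temperature."""

    temperature: float
    kcat_co2: float
    s_co: float
    k_c: float
    k_o: float


def arrhenius_value(tr: TemperatureResponse, t):
    """Evaluate a temperature response at ``t`` °C.

    Accepts a scalar or array temperature; returns the same shape. The
    exponent is ``(t − 25)·Ea·1000 / (298·R·(273 + t))`` with Ea converted
    from kJ to J mol⁻¹, so the returned value is exactly ``value_25`` at
    25 °C for any activation energy.

    Raises
    ------
    DomainError
        If any temperature falls outside −10..60 °C.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < _T_MIN) | (t_arr > _T_MAX)) or not np.all(np.isfinite(t_arr)):
        raise DomainError(
            f"temperature must lie in [{_T_MIN}, {_T_MAX}] °C, got {t!r}"
        )
    exponent = (t_arr - T_REF) * tr.e_a * 1000.0 / (298.0 * R_GAS * (273.0 + t_arr))
    out = tr.value_25 * np.exp(exponent)
    if np.ndim(t) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ArrheniusFit:
    """Result of a nonlinear Arrhenius fit."""

    response: TemperatureResponse
    residuals: np.ndarray = field(repr=False)
    rmse: float

    @property
    def value_25(self) -> float:
        return self.response.value_25

    @property
    def e_a(self) -> float:
        return self.response.e_a


def fit_arrhenius(temps, values) -> ArrheniusFit:
    """Fit value_25 and Ea of the Arrhenius relation by least squares.

    Parameters
    ----------
    temps, values:
        Assay temperatures (°C) and the measured parameter values. At least
        three distinct temperatures and strictly positive values are
        required.

    Returns
    -------
    ArrheniusFit
        The fitted :class:`TemperatureResponse` (with standard errors from
        the covariance of the fit, when defined) plus residuals and RMSE.

    Notes
    -----
    The initial guess comes from the log-linear form: ``ln v`` is linear in
    ``(t − 25)/(298·R·(273 + t))`` with slope ``Ea`` (J mol⁻¹), so the start
    point is deterministic and the noiseless round trip is exact to solver
    precision.
    """
    t = np.asarray(temps, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise InputError("temps and values must be 1-D arrays of equal length")
    if np.unique(t).size < 3:
        raise InputError("at least three distinct temperatures are required")
    if np.any(v <= 0.0) or not np.all(np.isfinite(v)):
        raise InputError("all parameter values must be positive and finite")
    if np.any((t < _T_MIN) | (t > _T_MAX)):
        raise DomainError(f"temperatures must lie in [{_T_MIN}, {_T_MAX}] °C")

    # Deterministic start from the log-linear form.
    x = (t - T_REF) / (298.0 * R_GAS * (273.0 + t))
    slope, intercept = np.polyfit(x, np.log(v), 1)
    p0 = [float(np.exp(intercept)), float(slope) / 1000.0]

    def model(tt, value_25, e_a):
        return value_25 * np.exp(
            (tt - T_REF) * e_a * 1000.0 / (298.0 * R_GAS * (273.0 + tt))
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(model, t, v, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise FitError(f"Arrhenius fit did not converge: {exc}") from exc

    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    se_25 = float(perr[0]) if np.isfinite(perr[0]) else None
    se_ea = float(perr[1]) if np.isfinite(perr[1]) else None
    resid = v - model(t, *popt)
    response = TemperatureResponse(float(popt[0]), float(popt[1]), se_25, se_ea)
    return ArrheniusFit(response, resid, float(np.sqrt(np.mean(resid**2))))


def kinetics_at_temperature(k: RubiscoKinetics, t: float) -> KineticConstants:
    """Evaluate all four constants of ``k`` at ``t`` °C."""
    return KineticConstants(
        temperature=float(t),
        kcat_co2=arrhenius_value(k.kcat_co2, t),
        s_co=arrhenius_value(k.s_co, t),
        k_c=arrhenius_value(k.k_c, t),
        k_o=arrhenius_value(k.k_o, t),
    )


def kc_apparent_o2(k_c: float, k_o: float, o: float) -> float:
    """Apparent Michaelis constant for CO2 in the presence of O2.

    ``K_C(1 + O/K_O)`` with all three arguments dissolved-phase µM. At zero
    oxygen this reduces to ``k_c``; competitive inhibition by O2 only ever
    increases the apparent constant.
    """
    if k_o <= 0.0:
        raise DomainError(f"k_o must be positive, got {k_o!r}")
    if k_c < 0.0 or o < 0.0:
        raise DomainError("k_c and o must be non-negative")
    return k_c * (1.0 + o / k_o)


def gamma_star_from_sco(s_co: float, o: float) -> float:
    """CO2 compensation point in the absence of day respiration, µM.

    Uses the standard relation Γ* = 0.5·O/S_C/O: at the compensation point
    one CO2 is released per two oxygenations, so Γ* is set by the oxygen
    concentration and the enzyme's relative specificity.
    """
    if s_co <= 0.0:
        raise DomainError(f"s_co must be positive, got {s_co!r}")
    if o < 0.0:
        raise DomainError(f"o must be non-negative, got {o!r}")
    return 0.5 * o / s_co


@dataclass(frozen=True)
class GasSolubility:
    """Temperature-indexed Henry coefficients, µM per µbar partial pressure.

    Coefficients must be strictly positive and decrease monotonically with
    temperature (gases are less soluble in warmer water). Lookup is by
    piecewise-linear interpolation; temperatures outside the table range are
    a :class:`DomainError`.
    """

    temperatures_c: np.ndarray
    coefficients: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_c, dtype=float)
        object.__setattr__(self, "temperatures_c", t)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise DomainError("solubility temperatures must be increasing")
        coefs = {}
        for gas, c in self.coefficients.items():
            c = np.asarray(c, dtype=float)
            if c.shape != t.shape:
                raise DomainError(f"coefficient table for {gas} has wrong length")
            if np.any(c <= 0):
                raise DomainError(f"coefficients for {gas} must be positive")
            if np.any(np.diff(c) >= 0):
                raise DomainError(
                    f"solubility of {gas} must decrease monotonically with "
                    "temperature"
                )
            coefs[gas.lower()] = c
        object.__setattr__(self, "coefficients", coefs)

    def coefficient(self, gas: str, t: float) -> float:
        gas = gas.lower()
        if gas not in self.coefficients:
            raise DomainError(f"unknown gas {gas!r}; have {sorted(self.coefficients)}")
        tmin, tmax = self.temperatures_c[0], self.temperatures_c[-1]
        t_arr = np.asarray(t, dtype=float)
        if np.any((t_arr < tmin) | (t_arr > tmax)):
            raise DomainError(
                f"temperature {t!r} outside solubility table range "
                f"[{tmin}, {tmax}] °C"
            )
        out = np.interp(t_arr, self.temperatures_c, self.coefficients[gas])
        return float(out) if np.ndim(t) == 0 else out


@lru_cache(maxsize=1)
def default_solubility() -> GasSolubility:
    """The bundled CO2/O2 solubility table (see data/solubility.csv)."""
    path = resources.files("rubiscotherm.data").joinpath("solubility.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#")
    return GasSolubility(
        temperatures_c=df["temp_c"].to_numpy(),
        coefficients={
            "co2": df["co2_um_per_ubar"].to_numpy(),
            "o2": df["o2_um_per_ubar"].to_numpy(),
        },
    )


def _partial_pressure_ubar(mole_fraction: float, pressure_kpa: float) -> float:
    # µmol mol⁻¹ × kPa → µbar:  mf·1e−6 · P·1e4 µbar = mf·P·1e−2
    return mole_fraction * pressure_kpa * 1e-2


def dissolved_concentration(
    mole_fraction: float,
    pressure_kpa: float,
    t: float,
    gas: str,
    sol: GasSolubility | None = None,
) -> float:
    """Dissolved concentration (µM) of a gas at a given mole fraction.

    ``mole_fraction`` is in µmol mol⁻¹, ``pressure_kpa`` the total air
    pressure in kPa. The partial pressure (µbar) is multiplied by the
    interpolated Henry coefficient at leaf temperature ``t``.
    """
    if pressure_kpa <= 0.0:
        raise DomainError(f"pressure must be positive, got {pressure_kpa!r}")
    if mole_fraction < 0.0:
        raise DomainError(f"mole fraction must be non-negative, got {mole_fraction!r}")
    sol = sol or default_solubility()
    return _partial_pressure_ubar(mole_fraction, pressure_kpa) * sol.coefficient(gas, t)


def mole_fraction_from_dissolved(
    concentration_um: float,
    pressure_kpa: float,
    t: float,
    gas: str,
    sol: GasSolubility | None = None,
) -> float:
    """Inverse of :func:`dissolved_concentration`: µM → µmol mol⁻¹."""
    if pressure_kpa <= 0.0:
        raise DomainError(f"pressure must be positive, got {pressure_kpa!r}")
    sol = sol or default_solubility()
    partial_ubar = concentration_um / sol.coefficient(gas, t)
    return partial_ubar / (pressure_kpa * 1e-2)


@dataclass(frozen=True)
class DerivedConstants:
    """Kinetics evaluated at leaf temperature, with derived model inputs.

    Dissolved-phase quantities are µM; ``gamma_star`` and ``k_m`` are the
    gas-phase (µmol mol⁻¹) values consumed by the FvCB model.
    """

    temperature: float
    o2_um: float
    kcat_co2: float
    s_co: float
    k_c_um: float
    k_o_um: float
    kc21_um: float
    gamma_star_um: float
    gamma_star: float
    k_m: float


def derived_constants(
    kin: RubiscoKinetics,
    t_leaf: float,
    o2_mole_fraction: float = 210000.0,
    pressure_kpa: float = 101.325,
    sol: GasSolubility | None = None,
) -> DerivedConstants:
    """Evaluate a kinetics set at leaf temperature and derive model inputs.

    Computes the four constants at ``t_leaf``, the dissolved O2 at the given
    mole fraction and pressure, the apparent ``K_C(1+O/K_O)`` and
    Γ* = 0.5·O/S_C/O in dissolved µM, and converts the latter two to
    gas-phase mole fractions through the Henry-law bridge.
    """
    sol = sol or default_solubility()
    consts = kinetics_at_temperature(kin, t_leaf)
    o2_um = dissolved_concentration(o2_mole_fraction, pressure_kpa, t_leaf, "o2", sol)
    kc21_um = kc_apparent_o2(consts.k_c, consts.k_o, o2_um)
    gamma_um = gamma_star_from_sco(consts.s_co, o2_um)
    return DerivedConstants(
        temperature=float(t_leaf),
        o2_um=o2_um,
        kcat_co2=consts.kcat_co2,
        s_co=consts.s_co,
        k_c_um=consts.k_c,
        k_o_um=consts.k_o,
        kc21_um=kc21_um,
        gamma_star_um=gamma_um,
        gamma_star=mole_fraction_from_dissolved(gamma_um, pressure_kpa, t_leaf, "co2", sol),
        k_m=mole_fraction_from_dissolved(kc21_um, pressure_kpa, t_leaf, "co2", sol),
    )
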