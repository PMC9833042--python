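"""Inverse estimation from gas-exchange curves.

Implements the Ethier–Livingston variant of A–C_i curve fitting in which
mesophyll conductance is finite: the ordered C_i values are split into a
low-C_i (Rubisco-limited) and a high-C_i (RuBP-regeneration-limited) limb,
(V_cmax, g_m) are fitted on the first and (J_max, g_m) on the second, and
the transition point is the split that minimises the difference between the
two g_m estimates. Also provides the Michaelis–Menten fit of the in vivo
apparent K_C at 21% O2 from A–C_c data, the initial-slope comparison, and
the percent-difference summaries used to contrast growth treatments.

R_d is always a measured input (taken from the curve metadata), never a
fitted parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import OptimizeWarning, curve_fit as _scipy_curve_fit


def curve_fit(*args, **kwargs):
    """scipy.optimize.curve_fit, silencing the covariance warning that
    exact (noise-free) fits trigger."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        return _scipy_curve_fit(*args, **kwargs)

from .exceptions import DomainError, FitError, InputError
from .fvcb import FvCBParameters, limb_a_net
from .kinetics import GasSolubility, RubiscoKinetics, derived_constants

__all__ = [
    "GasExchangeCurve",
    "AciFitResult",
    "MMFitResult",
    "SlopeFit",
    "fit_aci_ethier",
    "fit_mm_kc21",
    "initial_slope",
    "percent_difference",
    "summarize_groups",
]


@dataclass(eq=False)
class GasExchangeCurve:
    """One plant's ordered A–C_i record plus metadata.

    Per-record arrays (protocol order is preserved): ambient and
    substomatal CO2 ``c_a``/``c_i`` (µmol mol⁻¹), net assimilation ``a_net``
    (µmol CO2 m⁻² s⁻¹), stomatal conductance to water ``g_s``
    (mol H2O m⁻² s⁻¹), leaf temperature ``t_leaf`` (°C) and air ``pressure``
    (kPa). Metadata: plant id, growth/measurement labels, dark-measured day
    respiration ``r_d`` and optional Rubisco site content (µmol m⁻²).
    """

    c_a: np.ndarray
    c_i: np.ndarray
    a_net: np.ndarray
    g_s: np.ndarray
    t_leaf: np.ndarray
    pressure: np.ndarray
    plant_id: str = ""
    growth_label: str = ""
    meas_label: str = ""
    r_d: float = 0.0
    rubisco_sites: float | None = None

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("c_a", "c_i", "a_net", "g_s", "t_leaf", "pressure"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise InputError(f"{name} must be 1-D")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise InputError("all per-record arrays must have equal length")
            arrays[name] = arr
            setattr(self, name, arr)
        if n is None or n < 6:
            raise InputError(f"a curve needs at least 6 records, got {n}")
        positive = arrays["a_net"] > 0.0
        if np.any(arrays["c_i"][positive] >= arrays["c_a"][positive]):
            raise InputError("c_i must be below c_a wherever a_net > 0")
        if self.r_d < 0.0:
            raise InputError(f"r_d must be non-negative, got {self.r_d!r}")

    @property
    def n_records(self) -> int:
        return int(self.c_a.size)

    @property
    def mean_t_leaf(self) -> float:
        return float(np.mean(self.t_leaf))

    @property
    def mean_pressure(self) -> float:
        return float(np.mean(self.pressure))

    def a_at_ca(self, c_a: float = 400.0, atol: float = 1.0) -> float:
        """First recorded a_net at (approximately) the given C_a step."""
        idx = np.flatnonzero(np.abs(self.c_a - c_a) <= atol)
        if idx.size == 0:
            return math.nan
        return float(self.a_net[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "c_a": self.c_a,
                "c_i": self.c_i,
                "a_net": self.a_net,
                "g_s": self.g_s,
                "t_leaf": self.t_leaf,
                "pressure": self.pressure,
            }
        )


@dataclass(frozen=True)
class AciFitResult:
    """Result of the transition-point (Ethier) A–C_i fit."""

    params: FvCBParameters
    transition_ci: float
    gm_rubisco: float
    gm_rubp: float
    rmse: float
    n_points_per_limb: tuple[int, int]
    criterion: float
    gamma_star: float
    k_m: float


@dataclass(frozen=True)
class MMFitResult:
    """Michaelis–Menten fit of gross assimilation against C_c."""

    kc21_apparent: float
    vmax_term: float
    se_kc21: float | None
    se_vmax: float | None
    rmse: float
    n_points: int


@dataclass(frozen=True)
class SlopeFit:
    """Ordinary least-squares initial slope of A_N against C_c."""

    slope: float
    se: float
    intercept: float
    n_points: int


def _start_vmax(ci, gross, gamma, kd) -> float:
    """Deterministic start value: linear fit of the infinite-g_m limb."""
    f = (ci - gamma) / (ci + kd)
    denom = float(np.sum(f * f))
    if denom <= 0.0:
        return 50.0
    return float(np.clip(np.sum(f * gross) / denom, 1.0, 2000.0))


def fit_aci_ethier(
    curve: GasExchangeCurve,
    kin: RubiscoKinetics,
    o2_mole_fraction: float = 210000.0,
    *,
    sol: GasSolubility | None = None,
    min_points_per_limb: int = 2,
    gm_init: float = 0.15,
    gm_bounds: tuple[float, float] = (1e-3, 5.0),
) -> AciFitResult:
    """Estimate V_cmax, J_max and g_m from an A–C_i curve.

    Γ* and the effective Michaelis constant are evaluated at the curve's
    mean leaf temperature from the supplied Rubisco kinetics; ``r_d`` is the
    curve's measured dark respiration. Candidate transitions are the
    observed splits of the C_i-sorted records that leave at least
    ``min_points_per_limb`` points on each limb (2 = the number of free
    parameters per limb; the printed CO2 protocols keep the
    regeneration-limited region short). For each candidate split,
    (V_cmax, g_m) are fitted to the low limb and (J_max, g_m) to the high
    limb; the returned split minimises |g_m(rubisco) − g_m(regeneration)|
    and the reported ``params.g_m`` is the mean of the two limb estimates.

    Raises
    ------
    InputError
        Fewer than 6 usable records.
    FitError
        No candidate split converged; the message lists per-split
        diagnostics.
    """
    n = curve.n_records
    if min_points_per_limb < 2:
        raise InputError("min_points_per_limb must be at least 2")
    if n < 2 * min_points_per_limb or n < 6:
        raise InputError(f"need at least {max(6, 2 * min_points_per_limb)} records, got {n}")

    d = derived_constants(
        kin, curve.mean_t_leaf, o2_mole_fraction, curve.mean_pressure, sol
    )
    gamma, km = d.gamma_star, d.k_m
    rd = curve.r_d

    order = np.argsort(curve.c_i, kind="stable")
    ci = curve.c_i[order]
    a = curve.a_net[order]
    gross = a + rd

    gm_lo, gm_hi = gm_bounds
    lower = [1e-6, gm_lo]
    upper = [5000.0, gm_hi]

    def rub_model(ci_arr, v, gm):
        return limb_a_net(ci_arr, v, km, gamma, rd, gm)

    def rubp_model(ci_arr, j, gm):
        return limb_a_net(ci_arr, j / 4.0, 2.0 * gamma, gamma, rd, gm)

    candidates = []
    failures = []
    for k in range(min_points_per_limb, n - min_points_per_limb + 1):
        lo, hi = slice(0, k), slice(k, n)
        try:
            v0 = _start_vmax(ci[lo], gross[lo], gamma, km)
            (v, gm_r), _ = curve_fit(
                rub_model, ci[lo], a[lo], p0=[v0, gm_init],
                bounds=(lower, upper), maxfev=20000,
            )
            j0 = 4.0 * _start_vmax(ci[hi], gross[hi], gamma, 2.0 * gamma)
            (j, gm_j), _ = curve_fit(
                rubp_model, ci[hi], a[hi], p0=[min(j0, 5000.0), gm_init],
                bounds=(lower, upper), maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            failures.append(f"split {k}: {exc}")
            continue
        resid = np.concatenate(
            [a[lo] - rub_model(ci[lo], v, gm_r), a[hi] - rubp_model(ci[hi], j, gm_j)]
        )
        candidates.append(
            {
                "k": k,
                "v_cmax": float(v),
                "gm_rubisco": float(gm_r),
                "j_max": float(j),
                "gm_rubp": float(gm_j),
                "criterion": abs(float(gm_r) - float(gm_j)),
                "rmse": float(np.sqrt(np.mean(resid**2))),
            }
        )

    if not candidates:
        raise FitError(
            "no candidate transition converged:\n" + "\n".join(failures)
        )

    best = min(candidates, key=lambda c: c["criterion"])
    k = best["k"]
    gm_mean = 0.5 * (best["gm_rubisco"] + best["gm_rubp"])
    params = FvCBParameters(
        v_cmax=best["v_cmax"],
        j_max=best["j_max"],
        r_d=rd,
        g_m=gm_mean,
        gamma_star=gamma,
        k_m=km,
    )
    return AciFitResult(
        params=params,
        transition_ci=0.5 * (ci[k - 1] + ci[k]),
        gm_rubisco=best["gm_rubisco"],
        gm_rubp=best["gm_rubp"],
        rmse=best["rmse"],
        n_points_per_limb=(k, n - k),
        criterion=best["criterion"],
        gamma_star=gamma,
        k_m=km,
    )


def fit_mm_kc21(
    curve: GasExchangeCurve,
    g_m: float,
    gamma_star: float,
    *,
    c_c=None,
    mask=None,
    normalise_by_sites: bool = False,
) -> MMFitResult:
    """Fit the in vivo apparent K_C at 21% O2 from an A–C_c curve.

    Gross assimilation ``A_N + R_d`` is regressed against the
    Michaelis–Menten form ``vmax·(C_c − Γ*)/(C_c + K_C21%O2)`` with Γ*
    fixed. ``C_c`` is inferred as ``C_i − A_N/g_m`` unless supplied
    explicitly (it must then use the same units as ``gamma_star``). An
    optional boolean ``mask`` restricts the fit to a subset of records
    (e.g. the Rubisco-limited portion below the fitted transition). With
    ``normalise_by_sites`` the fitted ``vmax`` term is divided by the
    curve's Rubisco site content, so it reports the in vivo kcat per site.
    """
    if c_c is None:
        if g_m <= 0.0:
            raise DomainError(f"g_m must be positive, got {g_m!r}")
        c_c = curve.c_i - curve.a_net / g_m
    c_c = np.asarray(c_c, dtype=float)
    a_gross = curve.a_net + curve.r_d
    if c_c.shape != a_gross.shape:
        raise InputError("c_c must match the curve's record count")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a_gross.shape:
            raise InputError("mask must match the curve's record count")
        if int(np.sum(mask)) < 3:
            raise InputError("mask must retain at least 3 records")
        c_c, a_gross = c_c[mask], a_gross[mask]
    if np.any(c_c <= 0.0):
        raise InputError("all inferred c_c values must be positive")
    if float(np.max(np.abs(c_c - gamma_star))) < 1e-9 or float(
        np.max(np.abs(a_gross))
    ) < 1e-12:
        raise FitError("degenerate curve: no gross assimilation signal to fit")

    def model(cc, vmax, kc21):
        return vmax * (cc - gamma_star) / (cc + kc21)

    p0 = [max(1.5 * float(np.max(a_gross)), 1.0), max(float(np.median(c_c)), 1.0)]
    try:
        popt, pcov = curve_fit(
            model, c_c, a_gross, p0=p0,
            bounds=([1e-6, 1e-6], [1e5, 1e6]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Michaelis–Menten fit did not converge: {exc}") from exc

    vmax, kc21 = float(popt[0]), float(popt[1])
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    se_vmax = float(perr[0]) if np.isfinite(perr[0]) else None
    se_kc21 = float(perr[1]) if np.isfinite(perr[1]) else None
    resid = a_gross - model(c_c, *popt)
    if normalise_by_sites:
        if not curve.rubisco_sites or curve.rubisco_sites <= 0.0:
            raise InputError("normalise_by_sites requires positive rubisco_sites")
        vmax /= curve.rubisco_sites
        if se_vmax is not None:
            se_vmax /= curve.rubisco_sites
    return MMFitResult(
        kc21_apparent=kc21,
        vmax_term=vmax,
        se_kc21=se_kc21,
        se_vmax=se_vmax,
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_points=int(c_c.size),
    )


def initial_slope(c_c, a_net, c_c_max: float) -> SlopeFit:
    """OLS slope of A_N against C_c over the points with C_c ≤ ``c_c_max``.

    The initial slope of the CO2 response approximates the in vivo
    carboxylation efficiency (V_cmax/(K_m + Γ*) in the low-C_c limit).
    """
    c_c = np.asarray(c_c, dtype=float)
    a_net = np.asarray(a_net, dtype=float)
    if c_c.shape != a_net.shape or c_c.ndim != 1:
        raise InputError("c_c and a_net must be 1-D arrays of equal length")
    keep = c_c <= c_c_max
    if int(np.sum(keep)) < 3:
        raise InputError(
            f"need at least 3 points with c_c <= {c_c_max}, got {int(np.sum(keep))}"
        )
    res = stats.linregress(c_c[keep], a_net[keep])
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return SlopeFit(
        slope=float(res.slope),
        se=se,
        intercept=float(res.intercept),
        n_points=int(np.sum(keep)),
    )


def percent_difference(reference: float, other: float, mode: str = "reduction") -> float:
    """Percent contrast between two group means.

    ``reduction``: 100·(reference − other)/reference — "other is x% less
    than reference". ``excess``: 100·(reference − other)/other — "reference
    is x% larger than other".
    """
    if mode == "reduction":
        if reference == 0.0:
            raise DomainError("reference must be nonzero in mode='reduction'")
        return 100.0 * (reference - other) / reference
    if mode == "excess":
        if other == 0.0:
            raise DomainError("other must be nonzero in mode='excess'")
        return 100.0 * (reference - other) / other
    raise InputError(f"unknown mode {mode!r}; use 'reduction' or 'excess'")


def summarize_groups(
    df: pd.DataFrame,
    value_columns: list[str],
    group_columns: list[str] = ("growth_label", "meas_label"),
) -> pd.DataFrame:
    """Group means and standard errors of fitted parameters.

    Returns one row per group with ``<col>_mean``, ``<col>_se`` and ``n``.
    """
    group_columns = list(group_columns)
    grouped = df.groupby(group_columns, sort=True)
    out = grouped.size().rename("n").to_frame()
    for col in value_columns:
        out[f"{col}_mean"] = grouped[col].mean()
        out[f"{col}_se"] = grouped[col].sem(ddof=1)
    return out.reset_index()
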