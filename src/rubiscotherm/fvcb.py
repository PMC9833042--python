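"""Forward Farquhar–von Caemmerer–Berry (FvCB) assimilation model.

Net assimilation is the minimum of two potential rates: the Rubisco-limited
(carboxylation-limited) rate

    A_c = V_cmax (C_c − Γ*) / (C_c + K_m) − R_d

and the RuBP-regeneration-limited (electron-transport-limited) rate on the
NADPH basis with J = J_max at saturating light

    A_j = J_max (C_c − Γ*) / (4 C_c + 8 Γ*) − R_d.

All concentrations are gas-phase mole fractions (µmol mol⁻¹); dissolved-µM
kinetic constants cross into this module only through
:func:`rubiscotherm.kinetics.derived_constants`.

With a finite mesophyll conductance the chloroplast CO2 is
``C_c = C_i − A/g_m``; substituting into either limb gives a quadratic in A
whose lower root is the physically admissible branch (the Ethier–Livingston
substitution). ``g_m = math.inf`` is the sentinel for "no mesophyll
resistance" (C_c = C_i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, FitDomainError
from .kinetics import GasSolubility, RubiscoKinetics, derived_constants

__all__ = [
    "RUBISCO",
    "RUBP_REGENERATION",
    "FvCBParameters",
    "LimitedRate",
    "assimilation_cc",
    "assimilation_ci",
    "vc_response",
    "assimilation_per_rubisco",
    "parameters_from_kinetics",
    "limb_crossover_cc",
    "limb_a_net",
]

RUBISCO = "rubisco"
RUBP_REGENERATION = "rubp_regeneration"


@dataclass(frozen=True)
class FvCBParameters:
    """Parameter set of one modelled leaf.

    Units: ``v_cmax`` µmol CO2 m⁻² s⁻¹; ``j_max`` µmol e⁻ m⁻² s⁻¹; ``r_d``
    µmol CO2 m⁻² s⁻¹; ``g_m`` mol CO2 m⁻² s⁻¹ (``math.inf`` means
    C_c = C_i); ``gamma_star`` and ``k_m`` gas-phase µmol mol⁻¹.
    """

    v_cmax: float
    j_max: float
    r_d: float
    g_m: float
    gamma_star: float
    k_m: float

    def __post_init__(self) -> None:
        for name in ("v_cmax", "j_max", "r_d", "gamma_star", "k_m"):
            v = getattr(self, name)
            if v < 0.0 or (not math.isfinite(v)):
                raise DomainError(f"{name} must be finite and non-negative, got {v!r}")
        if self.g_m <= 0.0 or math.isnan(self.g_m):
            raise DomainError(f"g_m must be positive (or math.inf), got {self.g_m!r}")


@dataclass(frozen=True)
class LimitedRate:
    """Net rate, implied chloroplast CO2 and the limb that set the minimum."""

    a_net: float
    c_c: float
    limitation: str


def _carboxylation_limbs(p: FvCBParameters, c_c: float) -> tuple[float, float]:
    """Potential carboxylation rates W_c and W_j at C_c (without the
    photorespiratory ``1 − Γ*/C_c`` factor)."""
    w_c = p.v_cmax * c_c / (c_c + p.k_m) if (c_c + p.k_m) > 0 else 0.0
    denom_j = 4.0 * c_c + 8.0 * p.gamma_star
    w_j = p.j_max * c_c / denom_j if denom_j > 0 else 0.0
    return w_c, w_j


def _limb_net_cc(p: FvCBParameters, c_c: float, limb: str) -> float:
    if limb == RUBISCO:
        return p.v_cmax * (c_c - p.gamma_star) / (c_c + p.k_m) - p.r_d
    denom = 4.0 * c_c + 8.0 * p.gamma_star
    if denom <= 0.0:
        return -p.r_d
    return p.j_max * (c_c - p.gamma_star) / denom - p.r_d


def assimilation_cc(p: FvCBParameters, c_c: float) -> LimitedRate:
    """Net assimilation at a known chloroplast CO2 mole fraction.

    The limitation is decided on the carboxylation rates
    ``W_c = V_cmax·C_c/(C_c + K_m)`` and ``W_j = J_max·C_c/(4C_c + 8Γ*)``;
    the net rate of the limiting limb is ``(1 − Γ*/C_c)·W − R_d``, i.e. the
    limb expressions in the module docstring. Above Γ* this coincides with
    taking the smaller gross rate; below Γ* it keeps the low-CO2 region
    Rubisco-limited, as carboxylation (not RuBP supply) is what runs out.
    At C_c = Γ* both limbs give exactly −R_d. Ties are tagged
    Rubisco-limited.
    """
    if c_c < 0.0:
        raise DomainError(f"c_c must be non-negative, got {c_c!r}")
    w_c, w_j = _carboxylation_limbs(p, c_c)
    limb = RUBISCO if w_c <= w_j else RUBP_REGENERATION
    return LimitedRate(_limb_net_cc(p, c_c, limb), float(c_c), limb)


def limb_a_net(ci, vm: float, kd: float, gamma: float, rd: float, gm: float):
    """Net rate of one generalised limb with finite mesophyll conductance.

    The limb is written as gross = ``vm (C_c − gamma)/(C_c + kd)`` — the
    Rubisco limb has ``vm = V_cmax, kd = K_m``, the regeneration limb
    ``vm = J_max/4, kd = 2 Γ*``. Substituting ``C_c = C_i − A/g_m`` gives

        A² − A·[g_m(C_i + kd) + vm − r_d] + g_m·[vm(C_i − gamma)
            − r_d(C_i + kd)] = 0

    and the lower root is returned (vectorised over ``ci``). For positive
    ``vm``, ``gm`` and ``kd + gamma`` the discriminant is
    ``(g_m(C_i+kd) − vm + r_d)² + 4 g_m vm (kd + gamma) ≥ 0``; a negative
    discriminant therefore signals inconsistent parameters and raises
    :class:`FitDomainError`.
    """
    ci_arr = np.asarray(ci, dtype=float)
    b = gm * (ci_arr + kd) + vm - rd
    c = gm * (vm * (ci_arr - gamma) - rd * (ci_arr + kd))
    disc = b * b - 4.0 * c
    if np.any(disc < 0.0):
        raise FitDomainError(
            "negative discriminant in mesophyll-conductance quadratic; "
            f"parameters inconsistent (vm={vm}, kd={kd}, gamma={gamma}, "
            f"rd={rd}, gm={gm})"
        )
    root = np.sqrt(disc)
    # Lower root; the 2c/(b + sqrt) form avoids cancellation when b > 0
    # (e.g. very large g_m, where b - sqrt(disc) loses all precision).
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(b > 0.0, 2.0 * c / (b + root), 0.5 * (b - root))
    return float(a) if np.ndim(ci) == 0 else a


def assimilation_ci(p: FvCBParameters, c_i: float) -> LimitedRate:
    """Net assimilation at a substomatal CO2 mole fraction.

    With infinite ``g_m`` this is exactly :func:`assimilation_cc` at
    ``c_c = c_i``. Otherwise each limb's quadratic is solved and the limb
    with the smaller gross rate is returned together with its implied C_c.
    """
    if c_i < 0.0:
        raise DomainError(f"c_i must be non-negative, got {c_i!r}")
    if math.isinf(p.g_m):
        return assimilation_cc(p, c_i)
    # Solve the Rubisco-limb quadratic, then check the limitation rule at
    # its implied C_c; the self-consistent candidate is the fixed point of
    # A = assimilation_cc(C_i − A/g_m).
    a_c = limb_a_net(c_i, p.v_cmax, p.k_m, p.gamma_star, p.r_d, p.g_m)
    cc_c = c_i - a_c / p.g_m
    w_c, w_j = _carboxylation_limbs(p, max(cc_c, 0.0))
    if w_c <= w_j:
        return LimitedRate(a_c, cc_c, RUBISCO)
    a_j = limb_a_net(c_i, p.j_max / 4.0, 2.0 * p.gamma_star, p.gamma_star, p.r_d, p.g_m)
    return LimitedRate(a_j, c_i - a_j / p.g_m, RUBP_REGENERATION)


def vc_response(v_cmax: float, c, k_c21):
    """Michaelis–Menten carboxylation rate ``V_cmax·C/(C + K_C21%O2)``.

    Used to model carboxylation on an equal-enzyme basis (with
    ``kcat_co2`` standing in for V_cmax); any consistent concentration
    units may be used for ``c`` and ``k_c21``.
    """
    c_arr = np.asarray(c, dtype=float)
    k_arr = np.asarray(k_c21, dtype=float)
    if v_cmax < 0.0 or np.any(c_arr < 0.0) or np.any(k_arr < 0.0):
        raise DomainError("v_cmax, c and k_c21 must be non-negative")
    denom = c_arr + k_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0.0, v_cmax * c_arr / np.where(denom > 0, denom, 1.0), 0.0)
    if np.ndim(c) == 0 and np.ndim(k_c21) == 0:
        return float(out)
    return out


def assimilation_per_rubisco(a_n: float, r_d: float, rubisco_sites: float) -> float:
    """Gross assimilation per Rubisco catalytic site, s⁻¹.

    ``(A_N + R_d)/[Rubisco sites]`` expresses the leaf-level rate as an in
    vivo turnover per site, directly comparable with in vitro kcat.
    """
    if rubisco_sites <= 0.0:
        raise DomainError(f"rubisco_sites must be positive, got {rubisco_sites!r}")
    return (a_n + r_d) / rubisco_sites


def limb_crossover_cc(p: FvCBParameters) -> float:
    """C_c at which the two limbs give equal gross rates.

    Returns ``math.inf`` when the Rubisco limb is the minimum everywhere
    (J_max/4 ≥ V_cmax never releases the carboxylation limitation).
    """
    lead = p.v_cmax - p.j_max / 4.0
    if lead <= 0.0:
        return math.inf
    cc = (p.j_max * p.k_m / 4.0 - 2.0 * p.gamma_star * p.v_cmax) / lead
    return max(cc, p.gamma_star)


def parameters_from_kinetics(
    kin: RubiscoKinetics,
    t_leaf: float,
    v_cmax: float,
    j_max: float,
    r_d: float,
    g_m: float,
    o2_mole_fraction: float = 210000.0,
    pressure_kpa: float = 101.325,
    sol: GasSolubility | None = None,
) -> FvCBParameters:
    """Build :class:`FvCBParameters` from a kinetics set and leaf conditions.

    Γ* and the effective Michaelis constant are evaluated at ``t_leaf`` from
    the Arrhenius responses and converted to gas-phase mole fractions.
    """
    d = derived_constants(kin, t_leaf, o2_mole_fraction, pressure_kpa, sol)
    return FvCBParameters(
        v_cmax=v_cmax,
        j_max=j_max,
        r_d=r_d,
        g_m=g_m,
        gamma_star=d.gamma_star,
        k_m=d.k_m,
    )
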