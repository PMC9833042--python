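"""Synthetic gas-exchange and in vitro assay generator.

Emulates the study design the analysis expects: two growth temperatures
(cold, 10 °C air; warm, 30 °C air) crossed with two measurement
temperatures (cuvette 10 °C and 30 °C; leaf temperatures 8.8 and 27.4 °C),
the stepped C_a protocol of an open-system A–C_i measurement
(400, 200, 150, 100, 75, 50, 300, 400, 400, 500, 750, 1200, plus 1800 at
30 °C only), replicate plants per design cell, and temperature-series
assays of the four Rubisco kinetic constants.

Noise model: additive Gaussian noise on net assimilation (default
σ = 0.2 µmol m⁻² s⁻¹, matching the order of the replicate standard errors
of the reference means) and mean-one multiplicative lognormal noise on in
vitro rates (default CV = 5%). C_i is generated from C_a with a constant
draw-down ratio (default C_i/C_a = 0.7) plus a per-step stomatal jitter.

All generators are pure functions of (truth, cell, replicate): the same
seed reproduces identical data byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .fvcb import assimilation_ci, parameters_from_kinetics
from .kinetics import RubiscoKinetics, TemperatureResponse, arrhenius_value

__all__ = [
    "CA_SCHEDULE_10C",
    "CA_SCHEDULE_30C",
    "ASSAY_TEMPS",
    "CellTruth",
    "SyntheticTruth",
    "default_truth",
    "generate_aci_curve",
    "generate_kinetic_assay",
    "generate_study_dataset",
    "read_manifest",
]

#: Stepped ambient-CO2 protocol (µmol mol⁻¹) at the 10 °C measurement.
CA_SCHEDULE_10C = (400.0, 200.0, 150.0, 100.0, 75.0, 50.0, 300.0, 400.0, 400.0, 500.0, 750.0, 1200.0)
#: At 30 °C the protocol adds a final 1800 step.
CA_SCHEDULE_30C = CA_SCHEDULE_10C + (1800.0,)

#: In vitro assay temperatures (°C).
ASSAY_TEMPS = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0)

_KINETIC_PARAMETERS = ("kcat_co2", "s_co", "k_c", "k_o")


@dataclass(frozen=True)
class CellTruth:
    """Generating leaf parameters for one growth × measurement cell."""

    v_cmax: float
    j_max: float
    r_d: float
    g_m: float
    g_s: float
    t_leaf: float
    rubisco_sites: float


@dataclass(frozen=True)
class SyntheticTruth:
    """The complete generating parameter set of a simulated study.

    ``cells`` is keyed ``"<growth_label>:<meas_label>"`` (e.g. ``"10C:30"``)
    and ``kinetics`` by growth label. Noise parameters must be
    non-negative; a fixed ``seed`` makes every generated dataset
    byte-identical.
    """

    kinetics: dict[str, RubiscoKinetics]
    cells: dict[str, CellTruth]
    noise_sd_gas: float = 0.2
    noise_cv_assay: float = 0.05
    ci_ca_ratio: float = 0.7
    ci_ca_jitter_sd: float = 0.02
    o2_mole_fraction: float = 210000.0
    pressure_kpa: float = 101.325
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd_gas", "noise_cv_assay", "ci_ca_jitter_sd"):
            if getattr(self, name) < 0.0:
                raise InputError(f"{name} must be non-negative")
        if not 0.0 < self.ci_ca_ratio < 1.0:
            raise InputError("ci_ca_ratio must be in (0, 1)")

    def with_noise(self, noise_sd_gas=None, noise_cv_assay=None) -> "SyntheticTruth":
        kwargs = {}
        if noise_sd_gas is not None:
            kwargs["noise_sd_gas"] = noise_sd_gas
        if noise_cv_assay is not None:
            kwargs["noise_cv_assay"] = noise_cv_assay
        return replace(self, **kwargs)

    def cell_index(self, cell: str) -> int:
        return sorted(self.cells).index(cell)

    def growth_index(self, growth_label: str) -> int:
        return sorted(self.kinetics).index(growth_label)

    def to_dict(self) -> dict:
        return {
            "kinetics": {
                label: {
                    "label": kin.label,
                    **{
                        p: asdict(getattr(kin, p))
                        for p in _KINETIC_PARAMETERS
                    },
                }
                for label, kin in self.kinetics.items()
            },
            "cells": {key: asdict(cell) for key, cell in self.cells.items()},
            "noise_sd_gas": self.noise_sd_gas,
            "noise_cv_assay": self.noise_cv_assay,
            "ci_ca_ratio": self.ci_ca_ratio,
            "ci_ca_jitter_sd": self.ci_ca_jitter_sd,
            "o2_mole_fraction": self.o2_mole_fraction,
            "pressure_kpa": self.pressure_kpa,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        kinetics = {
            label: RubiscoKinetics(
                label=entry.get("label", label),
                **{
                    p: TemperatureResponse(**entry[p])
                    for p in _KINETIC_PARAMETERS
                },
            )
            for label, entry in d["kinetics"].items()
        }
        cells = {key: CellTruth(**cell) for key, cell in d["cells"].items()}
        return cls(
            kinetics=kinetics,
            cells=cells,
            noise_sd_gas=d["noise_sd_gas"],
            noise_cv_assay=d["noise_cv_assay"],
            ci_ca_ratio=d["ci_ca_ratio"],
            ci_ca_jitter_sd=d["ci_ca_jitter_sd"],
            o2_mole_fraction=d["o2_mole_fraction"],
            pressure_kpa=d["pressure_kpa"],
            seed=d["seed"],
        )


def default_truth(seed: int = 0, noise_sd_gas: float = 0.2, noise_cv_assay: float = 0.05) -> SyntheticTruth:
    """The bundled reference study design as a generating truth.

    Kinetics come from the bundled in vitro table (cold- and warm-grown
    rows) and the per-cell leaf parameters from the bundled reference
    photosynthesis means.
    """
    # Imported here: io reads the bundled fixtures and depends on the
    # container types above.
    from .io import builtin_kinetics, builtin_reference_values

    kin = builtin_kinetics()
    ref = builtin_reference_values()
    cells = {}
    for _, row in ref.iterrows():
        key = f"{row['growth_label']}:{row['meas_label']}"
        cells[key] = CellTruth(
            v_cmax=float(row["v_cmax"]),
            j_max=float(row["j_max"]),
            r_d=float(row["r_d"]),
            g_m=float(row["g_m"]),
            g_s=float(row["g_s"]),
            t_leaf=float(row["t_leaf_c"]),
            rubisco_sites=float(row["rubisco_sites"]),
        )
    kinetics = {label: kin[label] for label in ("10C", "30C")}
    return SyntheticTruth(
        kinetics=kinetics,
        cells=cells,
        noise_sd_gas=noise_sd_gas,
        noise_cv_assay=noise_cv_assay,
        seed=int(seed),
    )


def generate_aci_curve(truth: SyntheticTruth, cell: str, replicate: int = 0):
    """Generate one replicate A–C_i curve for a design cell.

    C_a follows the stepped protocol (with the duplicated 400 steps; the
    30 °C cells include the final 1800 step). C_i is C_a times the
    draw-down ratio with per-step jitter; A is the forward FvCB model at
    C_i plus additive Gaussian noise of sd ``truth.noise_sd_gas``. The g_s
    column is back-calculated from the CO2 supply function where assimilation is
    positive, and the cell's reference g_s elsewhere.
    """
    from .fitting import GasExchangeCurve

    if cell not in truth.cells:
        raise InputError(f"unknown design cell {cell!r}; have {sorted(truth.cells)}")
    ct = truth.cells[cell]
    growth_label, meas_label = cell.split(":", 1)
    schedule = np.array(
        CA_SCHEDULE_30C if meas_label == "30" else CA_SCHEDULE_10C, dtype=float
    )
    n = schedule.size
    rng = np.random.default_rng([int(truth.seed), truth.cell_index(cell), int(replicate)])

    ratio = np.clip(
        truth.ci_ca_ratio + rng.normal(0.0, truth.ci_ca_jitter_sd, n), 0.40, 0.95
    )
    c_i = schedule * ratio
    params = parameters_from_kinetics(
        truth.kinetics[growth_label],
        ct.t_leaf,
        v_cmax=ct.v_cmax,
        j_max=ct.j_max,
        r_d=ct.r_d,
        g_m=ct.g_m,
        o2_mole_fraction=truth.o2_mole_fraction,
        pressure_kpa=truth.pressure_kpa,
    )
    a_model = np.array([assimilation_ci(params, ci).a_net for ci in c_i])
    a_net = a_model + rng.normal(0.0, 1.0, n) * truth.noise_sd_gas

    drawdown = schedule - c_i
    with np.errstate(divide="ignore", invalid="ignore"):
        g_s = np.where(a_net > 0.05, 1.6 * a_net / np.where(drawdown > 0, drawdown, 1.0), ct.g_s)
    return GasExchangeCurve(
        c_a=schedule,
        c_i=c_i,
        a_net=a_net,
        g_s=g_s,
        t_leaf=np.full(n, ct.t_leaf),
        pressure=np.full(n, truth.pressure_kpa),
        plant_id=f"{growth_label}-{meas_label}-r{int(replicate)}",
        growth_label=growth_label,
        meas_label=meas_label,
        r_d=ct.r_d,
        rubisco_sites=ct.rubisco_sites,
    )


def generate_kinetic_assay(
    truth: SyntheticTruth,
    growth_label: str,
    temps=ASSAY_TEMPS,
    reps: int = 1,
) -> pd.DataFrame:
    """Simulate in vitro temperature assays of the four kinetic constants.

    Per temperature, parameter and replicate, the Arrhenius truth value is
    multiplied by mean-one lognormal noise with CV ``truth.noise_cv_assay``
    (CV = 0 reproduces the Arrhenius values exactly).
    """
    if growth_label not in truth.kinetics:
        raise InputError(
            f"unknown growth label {growth_label!r}; have {sorted(truth.kinetics)}"
        )
    if reps < 1:
        raise InputError(f"reps must be >= 1, got {reps}")
    kin = truth.kinetics[growth_label]
    rng = np.random.default_rng(
        [int(truth.seed), 1000 + truth.growth_index(growth_label)]
    )
    cv = truth.noise_cv_assay
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    rows = []
    for t in temps:
        for parameter in _KINETIC_PARAMETERS:
            value = arrhenius_value(getattr(kin, parameter), t)
            draws = rng.normal(0.0, 1.0, int(reps))
            factors = np.exp(sigma * draws - 0.5 * sigma * sigma) if sigma > 0 else np.ones(int(reps))
            for rep, f in enumerate(factors):
                rows.append(
                    {
                        "growth_label": growth_label,
                        "temperature_c": float(t),
                        "parameter": parameter,
                        "replicate": rep,
                        "value": float(value * f),
                    }
                )
    return pd.DataFrame(rows)


def generate_study_dataset(truth: SyntheticTruth, n_replicates: int, out_dir) -> Path:
    """Write a full simulated study to ``out_dir``; returns the manifest path.

    Produces ``n_replicates`` curve files per design cell, one assay table
    per growth treatment, and ``manifest.json`` recording the generating
    truth, seed and package version.
    """
    from . import __version__
    from .io import write_gas_exchange_csv

    if n_replicates < 1:
        raise InputError(f"n_replicates must be >= 1, got {n_replicates}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for cell in sorted(truth.cells):
        growth_label, meas_label = cell.split(":", 1)
        for rep in range(n_replicates):
            curve = generate_aci_curve(truth, cell, rep)
            name = f"curve_{growth_label}_{meas_label}_r{rep}.csv"
            write_gas_exchange_csv(curve, out / name)
            files.append(name)
    for growth_label in sorted(truth.kinetics):
        assay = generate_kinetic_assay(truth, growth_label, reps=5)
        name = f"assay_{growth_label}.csv"
        assay.to_csv(out / name, index=False, float_format="%.10g")
        files.append(name)
    manifest = {
        "package": "rubiscotherm",
        "version": __version__,
        "seed": int(truth.seed),
        "n_replicates": int(n_replicates),
        "truth": truth.to_dict(),
        "files": files,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def read_manifest(path) -> tuple[SyntheticTruth, dict]:
    """Read a study manifest back; returns (truth, full manifest dict)."""
    d = json.loads(Path(path).read_text())
    return SyntheticTruth.from_dict(d["truth"]), d
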