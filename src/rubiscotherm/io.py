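"""File formats and configuration.

Curves, kinetics tables and fit reports are plain delimited text. Curve
files carry a ``#``-prefixed metadata header of ``key = value`` lines ahead
of the CSV body; numeric output is written with 6 significant digits so
reports diff cleanly and two runs with the same seed are byte-identical.
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError, SchemaError
from .fitting import GasExchangeCurve
from .kinetics import RubiscoKinetics, TemperatureResponse

__all__ = [
    "CURVE_COLUMNS",
    "read_gas_exchange_csv",
    "write_gas_exchange_csv",
    "read_kinetics_table",
    "write_kinetics_table",
    "builtin_kinetics",
    "builtin_reference_values",
    "write_report",
    "read_report",
    "RunConfig",
]

CURVE_COLUMNS = ("c_a", "c_i", "a_net", "g_s", "t_leaf", "pressure")

_KINETIC_PARAMETERS = ("kcat_co2", "s_co", "k_c", "k_o")

_META_FIELDS = {
    "plant_id": str,
    "growth_label": str,
    "meas_label": str,
    "r_d": float,
    "rubisco_sites": float,
}


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def read_gas_exchange_csv(path) -> GasExchangeCurve:
    """Read one curve file (``#`` metadata header + CSV body).

    Raises :class:`SchemaError` naming the first missing required column
    and :class:`ParseError` with a row number for non-numeric cells.
    Record order is preserved.
    """
    path = Path(path)
    meta: dict[str, object] = {}
    body_lines = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                key = key.strip().lower()
                if key in _META_FIELDS:
                    caster = _META_FIELDS[key]
                    try:
                        meta[key] = caster(value.strip())
                    except ValueError as exc:
                        raise ParseError(
                            f"{path.name}: bad metadata value for {key!r}: {value!r}"
                        ) from exc
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise SchemaError(f"{path.name}: no data rows")
    df = pd.read_csv(_io.StringIO("\n".join(body_lines)), dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in CURVE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column '{col}'")
    numeric = {}
    for col in CURVE_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} in "
                f"column '{col}', data row {row + 1}"
            )
        numeric[col] = converted.to_numpy(dtype=float)
    return GasExchangeCurve(**numeric, **meta)


def write_gas_exchange_csv(curve: GasExchangeCurve, path) -> None:
    path = Path(path)
    lines = [
        f"# plant_id = {curve.plant_id}",
        f"# growth_label = {curve.growth_label}",
        f"# meas_label = {curve.meas_label}",
        f"# r_d = {_fmt(curve.r_d)}",
    ]
    if curve.rubisco_sites is not None:
        lines.append(f"# rubisco_sites = {_fmt(curve.rubisco_sites)}")
    lines.append(",".join(CURVE_COLUMNS))
    for i in range(curve.n_records):
        lines.append(
            ",".join(_fmt(float(getattr(curve, col)[i])) for col in CURVE_COLUMNS)
        )
    path.write_text("\n".join(lines) + "\n")


def read_kinetics_table(path) -> dict[str, RubiscoKinetics]:
    """Read a long-format kinetics table into per-label kinetics sets.

    Expected columns: label, parameter, value_25, se_25, ea_kj_mol, se_ea;
    each label must provide all four constants.
    """
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = ("label", "parameter", "value_25", "ea_kj_mol")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"kinetics table missing required column '{col}'")
    out: dict[str, RubiscoKinetics] = {}
    for label, group in df.groupby("label", sort=True):
        responses = {}
        for _, row in group.iterrows():
            parameter = str(row["parameter"]).strip().lower()
            if parameter not in _KINETIC_PARAMETERS:
                raise SchemaError(f"unknown kinetic parameter {parameter!r}")
            def _opt(name):
                if name not in row or pd.isna(row[name]):
                    return None
                return float(row[name])
            responses[parameter] = TemperatureResponse(
                value_25=float(row["value_25"]),
                e_a=float(row["ea_kj_mol"]),
                se_25=_opt("se_25"),
                se_ea=_opt("se_ea"),
            )
        missing = set(_KINETIC_PARAMETERS) - set(responses)
        if missing:
            raise SchemaError(f"label {label!r} missing parameters {sorted(missing)}")
        out[str(label)] = RubiscoKinetics(label=str(label), **responses)
    return out


def write_kinetics_table(kinetics: dict[str, RubiscoKinetics], path) -> None:
    rows = []
    for label in sorted(kinetics):
        kin = kinetics[label]
        for parameter in _KINETIC_PARAMETERS:
            tr = getattr(kin, parameter)
            rows.append(
                {
                    "label": label,
                    "parameter": parameter,
                    "value_25": tr.value_25,
                    "se_25": tr.se_25,
                    "ea_kj_mol": tr.e_a,
                    "se_ea": tr.se_ea,
                }
            )
    write_report(pd.DataFrame(rows), path)


def builtin_kinetics() -> dict[str, RubiscoKinetics]:
    """The bundled reference in vitro kinetics (labels 10C, 20C, 30C)."""
    path = resources.files("rubiscotherm.data").joinpath("reference_kinetics.csv")
    with resources.as_file(path) as p:
        return read_kinetics_table(p)


def builtin_reference_values() -> pd.DataFrame:
    """The bundled leaf-level reference means (A400, g_s, V_cmax, ...)."""
    path = resources.files("rubiscotherm.data").joinpath("reference_photosynthesis.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#", dtype={"growth_label": str, "meas_label": str})
    return df


def write_report(results, path) -> None:
    """Write a fit report with deterministic column order and formatting.

    ``results`` is a DataFrame or a list of dicts; floats are rendered with
    6 significant digits.
    """
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def render(x):
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return ""
        if isinstance(x, (float, np.floating)):
            return _fmt(float(x))
        return str(x)

    lines = [",".join(str(c) for c in df.columns)]
    for _, row in df.iterrows():
        lines.append(",".join(render(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class RunConfig:
    """Validated run configuration for the CLI pipeline."""

    input_dir: str = "."
    output_dir: str = "."
    kinetics_table: str | None = None
    solubility_table: str | None = None
    o2_mole_fraction: float = 210000.0
    pressure_kpa: float = 101.325
    seed: int = 0
    replicates: int = 5
    noise_sd_gas: float = 0.2
    noise_cv_assay: float = 0.05
    min_points_per_limb: int = 2
    normalise_by_sites: bool = False
    gross_plot: bool = False

    _BOUNDS = {
        "o2_mole_fraction": (0.0, 1e6),
        "pressure_kpa": (10.0, 200.0),
        "seed": (0, 2**31 - 1),
        "replicates": (1, 10000),
        "noise_sd_gas": (0.0, 100.0),
        "noise_cv_assay": (0.0, 1.0),
        "min_points_per_limb": (2, 100),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"config field {name}={v!r} outside [{lo}, {hi}]")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
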