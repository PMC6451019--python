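"""Parameter-table and CSV input/output.

Parameter tables are YAML with a strict schema (unknown or missing keys are
errors naming the key).  The package ships a default table with the
reference morphometry and sensitivities for the ab3, ab4 and ab5 sensilla.
CSV files carry a versioned schema comment on the first line and explicit
units in every numeric column header.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .circuit import CommonParams, ORNSpec, ParameterError, SensillumModel, calibrate_resting

__all__ = [
    "ConfigError",
    "ParamTables",
    "load_params",
    "save_params",
    "default_params",
    "write_csv",
    "read_dataset_csv",
]

_SCHEMA_VERSION = 1
_COMMON_KEYS = ("E_A", "V_0", "rho_s", "rho_d0", "n", "g_max")
_ORN_KEYS = ("A_s", "A_d", "k_od", "A_d_is_measured")
DATA_SCHEMA_COMMENT = "# ephaptic-data v1: sensillum,orn,odorant,x_log10_dilution,replicate,lfp_mV"
CURVE_SCHEMA_COMMENT = ("# ephaptic-curves v1: sensillum,orn,background_fraction,"
                        "x_log10_dilution,lfp_mV,vm_active_mV,vm_neighbor_mV")


class ConfigError(ValueError):
    """A parameter file is malformed; the message names the offending key."""


@dataclass(frozen=True)
class ParamTables:
    """A common-parameter block plus per-sensillum ORN pairs."""

    common: CommonParams
    sensilla: dict[str, tuple[ORNSpec, ORNSpec]]

    def model(self, name: str) -> SensillumModel:
        """Calibrated circuit model for one sensillum."""
        if name not in self.sensilla:
            raise ConfigError(f"unknown sensillum {name!r}; have {sorted(self.sensilla)}")
        o1, o2 = self.sensilla[name]
        return calibrate_resting(self.common, o1, o2, name=name)

    def models(self) -> dict[str, SensillumModel]:
        return {name: self.model(name) for name in sorted(self.sensilla)}


def _require_number(mapping: dict, key: str, context: str) -> float:
    if key not in mapping:
        raise ConfigError(f"{context}: missing key {key!r}")
    v = mapping[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ConfigError(f"{context}: value for {key!r} must be numeric, got {v!r}")
    return float(v)


def _parse(doc: dict, origin: str) -> ParamTables:
    if not isinstance(doc, dict):
        raise ConfigError(f"{origin}: parameter file must be a mapping")
    unknown = set(doc) - {"schema", "common", "sensilla"}
    if unknown:
        raise ConfigError(f"{origin}: unknown top-level keys {sorted(unknown)}")
    if doc.get("schema") != _SCHEMA_VERSION:
        raise ConfigError(f"{origin}: schema must be {_SCHEMA_VERSION}, got {doc.get('schema')!r}")

    common_doc = doc.get("common")
    if not isinstance(common_doc, dict):
        raise ConfigError(f"{origin}: missing or malformed 'common' block")
    unknown = set(common_doc) - set(_COMMON_KEYS)
    if unknown:
        raise ConfigError(f"{origin}: unknown common keys {sorted(unknown)}")
    try:
        common = CommonParams(**{k: _require_number(common_doc, k, f"{origin}:common")
                                 for k in _COMMON_KEYS})
    except ParameterError as exc:
        raise ConfigError(f"{origin}: {exc}") from exc

    sens_doc = doc.get("sensilla")
    if not isinstance(sens_doc, dict) or not sens_doc:
        raise ConfigError(f"{origin}: missing or empty 'sensilla' block")
    sensilla: dict[str, tuple[ORNSpec, ORNSpec]] = {}
    for name, pair in sens_doc.items():
        if not isinstance(pair, dict) or set(pair) != {"A", "B"}:
            raise ConfigError(f"{origin}:{name}: each sensillum needs exactly "
                              "the neurons 'A' and 'B'")
        orns = []
        for which in ("A", "B"):
            od = pair[which]
            ctx = f"{origin}:{name}.{which}"
            if not isinstance(od, dict):
                raise ConfigError(f"{ctx}: must be a mapping")
            unknown = set(od) - set(_ORN_KEYS)
            if unknown:
                raise ConfigError(f"{ctx}: unknown keys {sorted(unknown)}")
            measured = od.get("A_d_is_measured", False)
            if not isinstance(measured, bool):
                raise ConfigError(f"{ctx}: A_d_is_measured must be boolean")
            a_d = None
            if "A_d" in od and od["A_d"] is not None:
                a_d = _require_number(od, "A_d", ctx)
            try:
                orns.append(ORNSpec(label=f"{name}{which}",
                                    A_s=_require_number(od, "A_s", ctx),
                                    A_d=a_d,
                                    k_od=_require_number(od, "k_od", ctx),
                                    A_d_is_measured=measured))
            except ParameterError as exc:
                raise ConfigError(f"{ctx}: {exc}") from exc
        sensilla[name] = (orns[0], orns[1])
    return ParamTables(common=common, sensilla=sensilla)


def load_params(path: str | Path) -> ParamTables:
    """Load and validate a parameter table from a YAML file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse(doc, str(path))


def save_params(tables: ParamTables, path: str | Path) -> None:
    """Write a parameter table; save/load round-trips are value-identical
    and repeated saves are byte-identical."""
    doc = {
        "schema": _SCHEMA_VERSION,
        "common": {k: getattr(tables.common, k) for k in _COMMON_KEYS},
        "sensilla": {
            name: {
                which: {
                    "A_s": orn.A_s,
                    "A_d": orn.A_d,
                    "k_od": orn.k_od,
                    "A_d_is_measured": orn.A_d_is_measured,
                }
                for which, orn in zip(("A", "B"), pair)
            }
            for name, pair in sorted(tables.sensilla.items())
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)


def default_params() -> ParamTables:
    """The packaged reference parameter table (ab3, ab4, ab5)."""
    ref = resources.files("ephaptic").joinpath("data/default_params.yaml")
    doc = yaml.safe_load(ref.read_text())
    return _parse(doc, "packaged default")


def write_csv(frame: pd.DataFrame, path: str | Path, schema_comment: str) -> None:
    """Write a DataFrame as CSV with a leading schema-version comment line."""
    with open(path, "w", newline="") as fh:
        fh.write(schema_comment + "\n")
        frame.to_csv(fh, index=False)


def read_dataset_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
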