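"""Configuration loading, result serialization, and run manifests.

Config files are YAML or JSON with up to four sections::

    protocol:   # ProtocolConfig fields (mode, frequency_hz, coupling, ...)
    ionic:      # IonicParameters overrides
    ce:         # CEParameters overrides
    tissue:     # PassiveForceConfig overrides (ctn)

Every numeric constant is overridable by dotted path (``ce.kxb: 120``);
unknown keys are rejected with the offending path.  Time series are
written as CSV with a JSON sidecar documenting units; biomarkers and
manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .parameters import (CEParameters, IonicParameters, ModelParameters,
                         PassiveForceConfig, provenance)
from .protocols import ProtocolConfig, SimulationResult

__all__ = [
    "ConfigError", "load_config", "apply_overrides", "resolved_config_dict",
    "build_manifest", "save_manifest", "write_timeseries",
    "write_biomarkers", "write_sensitivity",
]

_SECTIONS = {
    "protocol": ProtocolConfig,
    "ionic": IonicParameters,
    "ce": CEParameters,
    "tissue": PassiveForceConfig,
}

#: units of the time-series columns (sidecar content)
_UNITS = {
    "t": "s", "V": "mV", "Cai": "mM", "CaSR": "mM", "Nai": "mM",
    "SL": "um", "intf": "normalized force x s",
    "Tension": "kPa", "F_active": "normalized", "F_passive": "normalized",
    "JCaBMyo": "mM/s", "Jup": "mM/s", "Jrel": "mM/s", "Jleak": "mM/s",
    "TropApr": "fraction", "SOVFThin": "fraction", "FrSBXB": "fraction",
}
_CURRENT_COLS = ("INa", "INaL", "ICaL", "If", "IK1", "IKr", "IKs", "Ito",
                 "INaCa", "INaK", "IpCa", "IbNa", "IbCa", "Istim")


class ConfigError(ValueError):
    """Invalid configuration; message lists the offending paths."""


def _coerce(section: str, cls, values: dict):
    if not isinstance(values, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    if section == "protocol" and values.get("max_step", 0.0) is None:
        values = {**values, "max_step": float("inf")}
    # PyYAML reads bare scientific notation like `2e-05` as a string;
    # coerce numeric-looking strings for float-typed fields
    types = {f.name: f.type for f in dataclasses.fields(cls)}
    coerced = {}
    for k, v in values.items():
        if isinstance(v, str) and "float" in str(types.get(k, "")):
            try:
                v = float(v)
            except ValueError:
                pass
        coerced[k] = v
    values = coerced
    valid = {f.name for f in dataclasses.fields(cls)}
    bad = sorted(set(values) - valid)
    if bad:
        raise ConfigError(
            f"unknown keys in section {section!r}: "
            + ", ".join(f"{section}.{k}" for k in bad))
    try:
        return cls(**values)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid values in section {section!r}: {exc}") from exc


def load_config(path=None, overrides: dict | None = None
                ) -> tuple[ProtocolConfig, ModelParameters]:
    """Load and validate a config file; missing sections use defaults.

    ``path=None`` or an empty file yields the full-default baseline.
    ``overrides`` maps dotted paths (e.g. ``"ce.kxb"``) to values and is
    applied after the file.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        raw = loaded
    if overrides:
        raw = apply_overrides(raw, overrides)

    unknown = sorted(set(raw) - set(_SECTIONS))
    if unknown:
        raise ConfigError("unknown config sections: " + ", ".join(unknown))

    built = {name: _coerce(name, cls, raw.get(name, {}))
             for name, cls in _SECTIONS.items()}
    protocol: ProtocolConfig = built["protocol"]
    params = ModelParameters(
        ionic=built["ionic"], ce=built["ce"], tissue=built["tissue"],
        coupling=protocol.coupling, isosarcometric=protocol.isosarcometric,
        ce_active=protocol.ce_active)
    params.validate()
    return protocol, params


def apply_overrides(tree: dict, overrides: dict) -> dict:
    """Apply ``{"section.key": value}`` overrides to a nested config dict."""
    import copy
    out = copy.deepcopy(tree)
    for dotted, value in overrides.items():
        parts = dotted.split(".")
        if len(parts) != 2 or parts[0] not in _SECTIONS:
            raise ConfigError(f"invalid override path {dotted!r} "
                              "(expected section.key)")
        out.setdefault(parts[0], {})[parts[1]] = value
    return out


def resolved_config_dict(protocol: ProtocolConfig,
                         params: ModelParameters) -> dict:
    """Fully resolved config tree (every constant explicit).

    Non-finite values (an unbounded ``max_step``) are serialized as null
    for JSON compatibility; :func:`load_config` restores them.
    """
    proto = dataclasses.asdict(protocol)
    if not np.isfinite(proto.get("max_step", 0.0)):
        proto["max_step"] = None
    return {
        "protocol": proto,
        "ionic": dataclasses.asdict(params.ionic),
        "ce": dataclasses.asdict(params.ce),
        "tissue": dataclasses.asdict(params.tissue),
    }


def build_manifest(protocol: ProtocolConfig, params: ModelParameters,
                   extra: dict | None = None) -> dict:
    """Run manifest: resolved config, provenance tags, version, host info."""
    man = {
        "package": "cardiomech",
        "version": _pkg_version,
        "created_unix": time.time(),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "platform": platform.platform(),
        "python": platform.python_version(),
        "config": resolved_config_dict(protocol, params),
        "provenance": provenance(params),
    }
    if extra:
        man["extra"] = extra
    return man


def save_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def write_timeseries(result: SimulationResult | pd.DataFrame, path) -> None:
    """CSV time series plus a ``<name>.units.json`` sidecar."""
    df = result.data if isinstance(result, SimulationResult) else result
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    units = {c: _UNITS.get(c, "A/F" if c in _CURRENT_COLS else "dimensionless")
             for c in df.columns}
    path.with_suffix(path.suffix + ".units.json").write_text(
        json.dumps(units, indent=2, sort_keys=True))


def write_biomarkers(biomarkers, path) -> None:
    """Biomarker set (or plain dict) as JSON; NaN serialized as null."""
    d = biomarkers.to_dict() if hasattr(biomarkers, "to_dict") else dict(biomarkers)
    clean = {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
             for k, v in d.items()}
    Path(path).write_text(json.dumps(clean, indent=2, sort_keys=True))


def write_sensitivity(result, directory, stem: str = "sensitivity") -> None:
    """Long-format CSV plus wide S and r matrices for a SensitivityResult."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    result.long_format().to_csv(directory / f"{stem}_long.csv", index=False,
                                float_format="%.8g")
    result.S.to_csv(directory / f"{stem}_S.csv", float_format="%.8g")
    result.r.to_csv(directory / f"{stem}_r.csv", float_format="%.8g")
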