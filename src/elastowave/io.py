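"""Configuration parsing, unit handling, and dispersion-curve CSV I/O.

Internally the package is strict SI (Pa, m, kg, s, Hz).  Config files and
the CLI accept the mixed units conventional in the application domains
(kPa, mm, mmHg, kHz, g/cm3) as strings with explicit unit suffixes, e.g.
``"11.11 kPa"``; plain numbers are taken as already-SI.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import DispersionCurve
from .errors import ConfigError, SchemaError

__all__ = [
    "parse_quantity",
    "RunConfig",
    "load_config",
    "write_curve",
    "read_curve",
]

MMHG_TO_PA = 133.322

UNIT_FACTORS = {
    # pressure / stress / modulus -> Pa
    "Pa": 1.0, "kPa": 1e3, "MPa": 1e6, "GPa": 1e9, "mmHg": MMHG_TO_PA,
    # length -> m
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6,
    # frequency -> Hz
    "Hz": 1.0, "kHz": 1e3,
    # density -> kg/m3
    "kg/m3": 1.0, "g/cm3": 1e3,
    # area -> m2
    "m2": 1.0, "cm2": 1e-4, "mm2": 1e-6,
}


def parse_quantity(value) -> float:
    """Convert a config value to SI.

    Numbers pass through; strings must be ``"<number> <unit>"`` (or a
    bare numeric string) with a known unit suffix.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        try:
            if len(parts) == 1:
                return float(parts[0])
            if len(parts) == 2:
                mag = float(parts[0])
                unit = parts[1]
                if unit not in UNIT_FACTORS:
                    raise ConfigError(
                        f"unknown unit {unit!r}; known: {sorted(UNIT_FACTORS)}"
                    )
                return mag * UNIT_FACTORS[unit]
        except ValueError as exc:
            raise ConfigError(f"cannot parse quantity {value!r}") from exc
    raise ConfigError(f"cannot parse quantity {value!r}")


_SCENARIOS = {"bulk", "plate", "beam", "cornea", "muscle", "synth", "invert"}

_REQUIRED_PARAMS = {
    "bulk": {"kappa", "mu_perp", "rho"},
    "plate": {"h", "rho", "E_perp", "nu_xy", "mu_perp"},
    "beam": {"rho", "E_par"},
    "cornea": {"iop", "radius", "thickness", "E_perp"},
    "muscle": {"sigma", "frequency"},
    "synth": {"model", "noise_level"},
    "invert": {"input", "model", "free"},
}

_TOP_KEYS = {"scenario", "parameters", "output", "seed", "log_level"}


@dataclass
class RunConfig:
    """Validated, SI-converted run configuration."""

    scenario: str
    parameters: dict = field(default_factory=dict)
    output: str | None = None
    seed: int | None = None
    log_level: str = "INFO"


def _convert(value):
    if isinstance(value, dict):
        return {k: _convert(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_convert(v) for v in value]
    if isinstance(value, str):
        try:
            return parse_quantity(value)
        except ConfigError:
            return value  # non-quantity strings (model names, paths) pass through
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    return value


def load_config(path) -> RunConfig:
    """Load and validate a TOML or JSON run configuration.

    Unknown top-level keys are rejected; missing required parameters for
    the scenario are reported by name; quantity strings are converted
    to SI on ingest.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".toml":
            raw = tomllib.loads(text)
        else:
            raw = json.loads(text)
    except (tomllib.TOMLDecodeError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path.name}: {exc}") from exc

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    scenario = raw.get("scenario")
    if scenario not in _SCENARIOS:
        raise ConfigError(
            f"scenario must be one of {sorted(_SCENARIOS)}, got {scenario!r}"
        )
    params = _convert(raw.get("parameters", {}))
    missing = _REQUIRED_PARAMS[scenario] - set(params)
    if missing:
        raise ConfigError(
            f"scenario {scenario!r} missing parameters: {sorted(missing)}"
        )
    seed = raw.get("seed")
    return RunConfig(
        scenario=scenario,
        parameters=params,
        output=raw.get("output"),
        seed=int(seed) if seed is not None else None,
        log_level=str(raw.get("log_level", "INFO")),
    )


_CURVE_COLUMNS = [
    "frequency_Hz",
    "k_rad_per_m_re",
    "k_rad_per_m_im",
    "c_m_per_s",
    "attenuation_Np_per_m",
]


def write_curve(path, curve: DispersionCurve) -> None:
    """Serialize a dispersion curve as CSV with a '#'-prefixed metadata
    header; floats are written with repr fidelity so the round trip is
    lossless."""
    path = Path(path)
    lines = ["# elastowave dispersion curve"]
    if curve.metadata:
        lines.append("# params: " + json.dumps(curve.metadata, sort_keys=True))
    lines.append(",".join(_CURVE_COLUMNS))
    cols = [
        curve.frequency,
        np.real(curve.wavenumber),
        np.imag(curve.wavenumber),
        curve.phase_speed,
        curve.attenuation,
    ]
    for row in zip(*cols):
        lines.append(",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_curve(path) -> DispersionCurve:
    """Read a curve written by :func:`write_curve`; full-precision
    round trip, with schema errors naming the offending row."""
    path = Path(path)
    metadata: dict = {}
    rows: list[list[float]] = []
    header: list[str] | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if body.startswith("params:"):
                metadata = json.loads(body[len("params:"):])
            continue
        parts = line.split(",")
        if header is None:
            header = parts
            if header != _CURVE_COLUMNS:
                raise SchemaError(
                    f"{path.name}:{lineno}: expected columns {_CURVE_COLUMNS}, "
                    f"got {header}"
                )
            continue
        if len(parts) != len(_CURVE_COLUMNS):
            raise SchemaError(f"{path.name}:{lineno}: expected "
                              f"{len(_CURVE_COLUMNS)} fields, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise SchemaError(f"{path.name}:{lineno}: non-numeric field") from exc
    if header is None:
        raise SchemaError(f"{path.name}: no header row")
    arr = np.asarray(rows, dtype=float) if rows else np.empty((0, 5))
    f = arr[:, 0]
    if f.size > 1 and not np.all(np.diff(f) > 0):
        bad = int(np.argmax(np.diff(f) <= 0)) + 2  # +1 header offset, +1 next row
        raise SchemaError(f"{path.name}: frequency not strictly increasing "
                          f"at data row {bad}")
    return DispersionCurve(
        frequency=f,
        wavenumber=arr[:, 1] + 1j * arr[:, 2],
        phase_speed=arr[:, 3],
        attenuation=arr[:, 4],
        metadata=metadata,
    )
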