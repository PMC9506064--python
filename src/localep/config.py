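"""Run configuration loading and the run manifest.

A run configuration is a YAML document with a ``scenario`` kind, an
optional ``seed``, an output directory, per-type parameter override
sections (``membrane``, ``cell``, ``substrate``, ``dna``,
``extracellular``, ``intracellular``, plus scenario-specific blocks)
and sweep grids.  Quantities accept mixed lab units (``"0.4 um"``,
``"2e6 1/cm^2"``, ``"10 ms"``) which are normalised to SI on load;
unknown keys are rejected outright.

Every run writes a ``manifest.json`` capturing the fully resolved
parameter set, the seed and the package version, so any output file can
be regenerated bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import yaml

from . import __version__
from .params import InvalidInputError, build_section
from .units import parse_quantity

__all__ = ["RunConfig", "ConfigError", "load_config", "write_manifest"]

SCENARIOS = ("unit-cell", "insert", "design-sweep", "fixture",
             "fig2d", "fig3", "table1-check")

_SECTION_KEYS = (
    "membrane",
    "cell",
    "substrate",
    "dna",
    "extracellular",
    "intracellular",
)
_TOP_KEYS = set(_SECTION_KEYS) | {
    "scenario",
    "seed",
    "output_dir",
    "voltage_grid",
    "duration",
    "pore_diameters",
    "porosities",
    "substrate_area",
    "geometry",
    "electrodes",
    "pulse",
    "noise_level",
    "true_resistance",
    "mesh_size",
}


class ConfigError(InvalidInputError):
    """Malformed run configuration."""


@dataclass
class RunConfig:
    """Fully resolved run description (SI units throughout)."""

    scenario: str
    seed: int = 0
    output_dir: Path = Path("localep-out")
    sections: dict = field(default_factory=dict)  # instantiated dataclasses
    options: dict = field(default_factory=dict)  # scenario-specific scalars/grids
    raw: dict = field(default_factory=dict)


def load_config(source) -> RunConfig:
    """Load and validate a configuration from a path, file object or
    pre-parsed mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    elif hasattr(source, "read"):
        data = yaml.safe_load(source)
    else:
        data = source
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    scenario = data.get("scenario")
    if scenario not in SCENARIOS:
        raise ConfigError(
            f"scenario must be one of {SCENARIOS}, got {scenario!r}"
        )
    try:
        seed = int(data.get("seed", 0))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"seed must be an integer: {exc}") from None

    sections = {}
    for key in _SECTION_KEYS:
        if key in data:
            try:
                sections[key] = build_section(key, data[key])
            except InvalidInputError as exc:
                raise ConfigError(f"section {key!r}: {exc}") from None

    options: dict = {}
    for key in ("voltage_grid", "pore_diameters", "porosities"):
        if key in data:
            try:
                options[key] = [parse_quantity(v) for v in data[key]]
            except Exception as exc:
                raise ConfigError(f"{key}: {exc}") from None
    for key in ("duration", "substrate_area", "noise_level",
                "true_resistance", "mesh_size"):
        if key in data:
            try:
                options[key] = parse_quantity(data[key])
            except Exception as exc:
                raise ConfigError(f"{key}: {exc}") from None
    for key in ("geometry", "electrodes", "pulse"):
        if key in data:
            if not isinstance(data[key], dict):
                raise ConfigError(f"{key} must be a mapping")
            options[key] = dict(data[key])

    return RunConfig(
        scenario=scenario,
        seed=seed,
        output_dir=Path(data.get("output_dir", "localep-out")),
        sections=sections,
        options=options,
        raw=data,
    )


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def write_manifest(config: RunConfig, resolved: dict, outdir: Path) -> Path:
    """Write the run manifest capturing the resolved parameters."""
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "localep",
        "version": __version__,
        "scenario": config.scenario,
        "seed": config.seed,
        "resolved_parameters": _jsonable(resolved),
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
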