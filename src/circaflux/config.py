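"""YAML configuration and run manifests for the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import yaml

from .stomatal_models import OscillatorParams
from .synthetic_data import SPECIES_DEFAULTS, ProtocolConfig, TrueParams

__all__ = ["load_config", "default_config", "config_hash", "RunManifest", "write_manifest"]

_PROTOCOL_KEYS = {f.name for f in dataclasses.fields(ProtocolConfig)}
_TRUTH_KEYS = {f.name for f in dataclasses.fields(TrueParams)}
_OSC_KEYS = {f.name for f in dataclasses.fields(OscillatorParams)}


def default_config() -> dict:
    """Default protocol and per-species ground-truth parameters as a dict."""
    return {
        "protocol": dataclasses.asdict(ProtocolConfig()),
        "species": {
            name: {
                **{k: v for k, v in dataclasses.asdict(p).items() if k != "osc"},
                "osc": dataclasses.asdict(p.osc),
            }
            for name, p in SPECIES_DEFAULTS.items()
        },
        "smoothing": {"basis_dim": 20, "ar1": True},
    }


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise KeyError(f"unknown keys in {where}: {sorted(unknown)}")


def parse_config(raw: dict) -> tuple[ProtocolConfig, dict[str, TrueParams], dict]:
    """Validate a config dict into protocol, species truths and options."""
    protocol_raw = dict(raw.get("protocol", {}))
    _check_keys(protocol_raw, _PROTOCOL_KEYS, "protocol")
    protocol = ProtocolConfig(**protocol_raw)
    species: dict[str, TrueParams] = {}
    for name, spec in dict(raw.get("species", {})).items():
        spec = dict(spec)
        osc_raw = dict(spec.pop("osc", {}))
        _check_keys(spec, _TRUTH_KEYS - {"osc"}, f"species.{name}")
        _check_keys(osc_raw, _OSC_KEYS, f"species.{name}.osc")
        kwargs = dict(spec)
        if osc_raw:
            kwargs["osc"] = OscillatorParams(**osc_raw)
        species[name] = TrueParams(**kwargs)
    if not species:
        species = dict(SPECIES_DEFAULTS)
    options = dict(raw.get("smoothing", {"basis_dim": 20, "ar1": True}))
    return protocol, species, options


def load_config(path: str | Path | None) -> tuple[ProtocolConfig, dict[str, TrueParams], dict]:
    """Load a YAML config; a missing path yields the defaults."""
    if path is None:
        return parse_config(default_config())
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)


def config_hash(raw: dict) -> str:
    return hashlib.sha256(json.dumps(raw, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: int
    version: str
    inputs: dict
    outputs: dict
    timestamp: str


def write_manifest(path: Path, manifest: RunManifest) -> None:
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True) + "\n")


def new_manifest(raw_config: dict, seed: int, inputs: dict, outputs: dict) -> RunManifest:
    from . import __version__

    return RunManifest(
        config_hash=config_hash(raw_config),
        seed=seed,
        version=__version__,
        inputs={k: str(v) for k, v in inputs.items()},
        outputs={k: str(v) for k, v in outputs.items()},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
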