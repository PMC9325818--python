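"""Run configuration: schema, validation, seed fan-out, manifests."""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import yaml

from salqsar import __version__

# Published schema: section -> {key: type}. Unknown sections or keys are
# rejected before any compute happens.
SCHEMA: dict[str, dict[str, type | tuple]] = {
    "": {
        "dataset": str,
        "output_dir": str,
        "seed": int,
        "split_fractions": list,
    },
    "gcnn": {
        "conv_sizes": list,
        "fc_size": int,
        "l2": (int, float),
        "epochs": int,
        "learning_rate": (int, float),
        "batch_size": int,
        "head_size": int,
    },
    "saliency": {
        "k_max": int,
        "top_m": int,
        "decay": (int, float),
        "decay_mode": str,
    },
    "clustering": {
        "d_c_percentile": (int, float),
        "min_points": int,
        "n_bits": int,
    },
    "search": {
        "iterations": int,
        "samples": int,
        "sigma": (int, float),
    },
    "generator": {
        "n": int,
        "motif": str,
        "label_noise": (int, float),
        "drift": (int, float),
        "active_fraction": (int, float),
    },
}


class ConfigError(ValueError):
    """Raised for unknown keys or badly typed values in a run config."""


def validate_config(raw: dict) -> dict:
    """Validate a config mapping against the published schema."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    for key, value in raw.items():
        if key in SCHEMA and key != "" and isinstance(value, dict):
            section = SCHEMA[key]
            for sub, sub_val in value.items():
                if sub not in section:
                    raise ConfigError(f"unknown config key: {key}.{sub}")
                if not isinstance(sub_val, section[sub]):
                    raise ConfigError(
                        f"config key {key}.{sub} has wrong type "
                        f"({type(sub_val).__name__})"
                    )
        elif key in SCHEMA[""]:
            if not isinstance(value, SCHEMA[""][key]):
                raise ConfigError(
                    f"config key {key} has wrong type ({type(value).__name__})"
                )
        else:
            raise ConfigError(f"unknown config key: {key}")
    return raw


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed.

    Fixed hash schedule so each pipeline stage is independently
    reproducible; results stay below 2**31.
    """
    return (global_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seed: int,
    inputs: list[str | Path] = (),
) -> Path:
    """Write the artifact manifest (inputs' checksums, config, version, seed)."""
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {str(p): file_checksum(p) for p in inputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
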