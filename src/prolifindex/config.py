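"""YAML run configuration and output manifests."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .io import RunConfig


def load_config(path) -> RunConfig:
    """Load a YAML key/value file into a :class:`~prolifindex.io.RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_manifest(out_dir, config: RunConfig, inputs: dict, extra: dict | None = None) -> Path:
    """Record inputs, thresholds, seed, and versions next to every run's outputs."""
    manifest = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "prolifindex_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {k: str(v) for k, v in inputs.items()},
    }
    if extra:
        manifest.update(extra)
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return out
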