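"""Trial-log and config I/O, plus run provenance manifests.

Trial logs are plain UTF-8 CSV with a mandatory header and the standard
record columns; configs are single YAML files; every CLI run writes a
JSON manifest recording the command, seeds, config hash, package
version, timestamps and file paths.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .records import COLUMNS, validate_frame

__all__ = ["read_trial_log", "write_trial_log", "read_config", "RunManifest", "write_manifest"]


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV; raises with row numbers on
    malformed rows, warns on an empty (header-only) file."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "group_label": str})
    if df.empty:
        warnings.warn(f"trial log {path} is empty", stacklevel=2)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial log missing columns: {missing}")
        return df[COLUMNS]
    validate_frame(df)
    return df[COLUMNS]


def write_trial_log(df: pd.DataFrame, path) -> None:
    validate_frame(df)
    df[COLUMNS].to_csv(path, index=False)


def read_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""
    started: str = ""
    finished: str = ""

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(manifest: RunManifest, path) -> None:
    from . import __version__

    manifest.package_version = __version__
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    d = asdict(manifest)
    d["config_hash"] = manifest.config_hash
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2, default=str)
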