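"""File formats and run manifests.

All artifacts are plain text: CSV for parameter and feature tables (header
mandatory, UTF-8, dot decimal, missing encoded as the literal ``NA``), JSON
for targets, metrics and run manifests. No operation mutates its input
files.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureTable
from .scoring import TargetStats

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_params",
    "write_params",
    "read_targets",
    "write_targets",
    "RunManifest",
]

NA_TOKEN = "NA"


class ParseError(ValueError):
    pass


def read_feature_table(path) -> FeatureTable:
    """Read a feature CSV; ``NA`` cells populate the missingness mask."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ParseError(f"duplicate column names {dups} in {path}")
    raw = pd.read_csv(path, keep_default_na=False, na_values=[NA_TOKEN], dtype=str)
    data = {}
    for col in raw.columns:
        try:
            data[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()
                            & raw[col].notna()][0]
            raise ParseError(
                f"non-numeric value {raw[col][bad]!r} at row {bad}, "
                f"column {col!r} in {path}"
            ) from None
    return FeatureTable(pd.DataFrame(data).astype(float))


def write_feature_table(table, path) -> None:
    data = table.data if isinstance(table, FeatureTable) else table
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data.to_csv(path, index=False, na_rep=NA_TOKEN)


def read_params(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if frame.columns.duplicated().any():
        raise ParseError(f"duplicate parameter columns in {path}")
    return frame.astype(float)


def write_params(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_targets(path) -> TargetStats:
    """Read per-feature mean/SD targets from JSON or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        frame = pd.DataFrame(payload).T if isinstance(payload, dict) else pd.DataFrame(payload)
        if "feature" in frame.columns:
            frame = frame.set_index("feature")
    else:
        frame = pd.read_csv(path)
        if "feature" not in frame.columns:
            raise ParseError(f"targets CSV needs a 'feature' column: {path}")
        frame = frame.set_index("feature")
    return TargetStats(frame)


def write_targets(targets: TargetStats, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        payload = {
            feat: {"mean": targets.mean(feat), "sd": targets.sd(feat)}
            for feat in targets.features
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        targets.stats.rename_axis("feature").to_csv(path)


class RunManifest:
    """Machine-readable record of a run: config snapshot, seeds, call counts
    and timestamps — enough to re-seed any stochastic stage."""

    def __init__(self, command: str, seed: int, config: dict | None = None):
        from . import __version__

        self.payload = {
            "command": command,
            "seed": int(seed),
            "config": _jsonable(config or {}),
            "version": __version__,
            "python": platform.python_version(),
            "started": datetime.now(timezone.utc).isoformat(),
            "counts": {},
            "outputs": [],
        }

    def count(self, name: str, value: int) -> None:
        self.payload["counts"][name] = int(value)

    def output(self, path) -> None:
        self.payload["outputs"].append(str(path))

    def write(self, path) -> None:
        self.payload["finished"] = datetime.now(timezone.utc).isoformat()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.payload, indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)
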