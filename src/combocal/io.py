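"""Result serialisation: tidy CSV tables and JSON run manifests."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .simulate import OperatingCharacteristics

__all__ = ["ocs_to_tidy", "write_results", "write_manifest"]


def ocs_to_tidy(design_name: str, ocs: dict[str, OperatingCharacteristics]) -> pd.DataFrame:
    """One row per (design, scenario, metric, value)."""
    rows = []
    for sid, oc in ocs.items():
        for metric, value in oc.as_dict().items():
            rows.append(
                {"design": design_name, "scenario": sid, "metric": metric, "value": value}
            )
    return pd.DataFrame(rows, columns=["design", "scenario", "metric", "value"])


def write_results(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def write_manifest(path: str | Path, *, config: dict, seed: int, scenario_ids: list[str]) -> Path:
    """JSON manifest sufficient to reproduce a run bitwise."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "combocal",
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "scenarios": scenario_ids,
        "config": _jsonable(config),
    }
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
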