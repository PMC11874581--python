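"""Study output writing: per-replicate CSV, summary CSV and a run manifest.

Outputs are deterministic: fixed column order, floats at 17 significant
digits (lossless for doubles), and a JSON manifest capturing the resolved
config, master seed and library versions, from which a run can be bit-reproduced.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .config import dump_config
from .simulate import SimulationConfig

__all__ = ["make_manifest", "write_summary"]


def make_manifest(
    cfg: SimulationConfig,
    master_seed: int,
    warnings: list[str] | None = None,
) -> dict[str, Any]:
    return {
        "artifact": "pwer",
        "version": __version__,
        "config": dump_config(cfg),
        "master_seed": int(master_seed),
        "replicate_seeding": "numpy SeedSequence(master_seed).spawn(replicates)",
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "warnings": warnings or [],
    }


def _format_csv(df: pd.DataFrame, index: bool) -> str:
    return df.to_csv(index=index, float_format="%.17g", lineterminator="\n")


def write_summary(
    replicates: pd.DataFrame,
    summary: pd.DataFrame,
    out_dir: str | Path,
    manifest: dict[str, Any],
) -> dict[str, Path]:
    """Write replicates.csv, summary.csv and manifest.json under ``out_dir``."""
    if len(replicates) == 0:
        raise IOError("no replicate results to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "replicates": out / "replicates.csv",
        "summary": out / "summary.csv",
        "manifest": out / "manifest.json",
    }
    paths["replicates"].write_text(_format_csv(replicates, index=False))
    summary = summary.rename_axis("metric")
    paths["summary"].write_text(_format_csv(summary, index=True))
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
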