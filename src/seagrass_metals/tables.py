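"""Delimited-text I/O: comma-separated tables and YAML run manifests.

All pipeline tables are UTF-8 CSV with a header row and "." decimal, one file
per table kind.  A manifest records the seed and every ground-truth parameter
of a simulation so any run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .mixing import SourceSummary
from .synthetic import SedimentTrendConfig, SimulationConfig


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:  # surface the line number
        raise ValueError(f"malformed delimited text in {path}: {exc}") from exc


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    """Serializable dict of a simulation config (tuple keys flattened)."""
    d = dataclasses.asdict(config)
    d["decomp_truth"] = {
        f"{metal}:{exp}": list(v) for (metal, exp), v in config.decomp_truth.items()
    }
    d["source_params"] = [dataclasses.asdict(s) for s in config.source_params]
    return d


def config_from_dict(d: dict[str, Any]) -> SimulationConfig:
    d = dict(d)
    d["decomp_truth"] = {
        tuple(k.split(":")): tuple(v) for k, v in d["decomp_truth"].items()
    }
    d["source_params"] = tuple(
        SourceSummary(s["label"], s["means"], s["sds"], s["n"])
        for s in d["source_params"]
    )
    st = d["sediment_trend"]
    d["sediment_trend"] = SedimentTrendConfig(
        params={
            pool: {el: tuple(v) for el, v in els.items()}
            for pool, els in st["params"].items()
        },
        d13c_range={k: tuple(v) for k, v in st["d13c_range"].items()},
        bottom_log_baseline=st["bottom_log_baseline"],
        bottom_d13c=tuple(st["bottom_d13c"]),
        bottom_log_sd=st["bottom_log_sd"],
        months=tuple(st["months"]),
        n_replicates=st["n_replicates"],
    )
    for key in ("c_range", "sampling_days"):
        d[key] = tuple(d[key])
    if d.get("c_decay") is not None:
        d["c_decay"] = tuple(d["c_decay"])
    return SimulationConfig(**d)


def write_manifest(payload: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def read_manifest(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
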