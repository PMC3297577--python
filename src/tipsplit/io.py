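"""Configuration, distance-table round-tripping and run manifests.

Formats: distances as CSV (hypha_id, kind, distance, trim, seed), fits and
manifests as JSON, configuration as TOML (JSON also accepted).  Units are
fixed throughout: micrometres, minutes, molecule counts.
"""

from __future__ import annotations

import hashlib
import json
import platform
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ModelParams
from .measurement import MeasurementParams
from .minimal_sim import TrimmedDistances

__all__ = [
    "read_config",
    "model_params_from_config",
    "measurement_params_from_config",
    "read_distances",
    "write_distances",
    "write_manifest",
]

_DIST_COLUMNS = ["hypha_id", "kind", "distance", "trim", "seed"]
_KINDS = {"tip_to_branch", "branch_to_branch"}


def read_config(path: str | Path) -> dict:
    """Read a TOML (or JSON) configuration file."""
    path = Path(path)
    data = path.read_bytes()
    if path.suffix == ".json":
        return json.loads(data)
    return tomllib.loads(data.decode())


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in [{where}]: {sorted(unknown)}")


def model_params_from_config(cfg: dict) -> ModelParams:
    """Build ModelParams from the [model] section (all keys validated)."""
    section = cfg.get("model", {})
    _check_keys(section, set(ModelParams.__dataclass_fields__), "model")
    return ModelParams(**section)


def measurement_params_from_config(cfg: dict) -> MeasurementParams:
    section = cfg.get("measurement", {})
    _check_keys(section, set(MeasurementParams.__dataclass_fields__), "measurement")
    return MeasurementParams(**section)


def write_distances(td: TrimmedDistances, path: str | Path) -> None:
    # %.17g keeps the round trip lossless at float64 precision
    td.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_distances(path: str | Path) -> TrimmedDistances:
    """Read a distances CSV, validating schema and value ranges.

    Malformed rows are reported with their (1-based, data) row numbers.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _DIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(df) == 0:
        return TrimmedDistances(L=float("nan"), tb=np.empty(0), bb=np.empty(0))
    bad_kind = ~df["kind"].isin(_KINDS)
    if bad_kind.any():
        rows = (df.index[bad_kind] + 1).tolist()[:5]
        raise ValueError(f"unknown kind at rows {rows}")
    neg = df["distance"] < 0
    if neg.any():
        rows = (df.index[neg] + 1).tolist()[:5]
        raise ValueError(f"negative distance at rows {rows}")
    over = df["distance"] > df["trim"] + 1e-9
    if over.any():
        rows = (df.index[over] + 1).tolist()[:5]
        raise ValueError(f"distance exceeds trim at rows {rows}")
    trims = df["trim"].unique()
    if len(trims) != 1:
        raise ValueError(f"mixed trim lengths in one file: {sorted(trims)}")
    tb = df[df["kind"] == "tip_to_branch"]
    bb = df[df["kind"] == "branch_to_branch"]
    seeds = df["seed"].unique()
    return TrimmedDistances(
        L=float(trims[0]),
        tb=tb["distance"].to_numpy(),
        bb=bb["distance"].to_numpy(),
        tb_hypha=tb["hypha_id"].to_numpy(),
        bb_hypha=bb["hypha_id"].to_numpy(),
        seed=int(seeds[0]) if len(seeds) == 1 and seeds[0] >= 0 else None,
    )


def write_manifest(out_dir: str | Path, config_path: str | Path | None, seed: int,
                   subcommand: str, extra: dict | None = None) -> Path:
    """Write a run manifest sufficient to reproduce the outputs byte-identically."""
    import tipsplit

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = None
    if config_path is not None:
        cfg_hash = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    manifest = {
        "subcommand": subcommand,
        "seed": seed,
        "config_sha256": cfg_hash,
        "tipsplit_version": getattr(tipsplit, "__version__", "unknown"),
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    if extra:
        manifest.update(extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
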