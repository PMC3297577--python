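"""Synthetic still-image and time-lapse datasets with known ground truth.

The generator runs the minimal simulator per hypha (each with its own tip
speed drawn from a positive-truncated normal around the population mean) and
converts the hidden state into what a microscopist can actually measure on a
still image: the visible segment length, each emerged branch's present
distance from the tip, and each branch's length grown under the ramped speed
profile.  The true emergence distances, per-hypha speeds and generator
configuration are retained as hidden ground truth so every downstream stage
(back-calculation, trimming, fitting) can be validated end to end.

What it does not emulate: pixel-level imaging, fluorescence noise, focus
detectability thresholds, or hyphae curving out of the focal plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ModelParams
from .measurement import MeasurementParams, branch_age_to_length
from .minimal_sim import _simulate_records

__all__ = ["StillImageDataset", "Timelapse", "generate_still_images", "generate_timelapse"]


@dataclass
class StillImageDataset:
    """Synthetic analogue of the experimental still-image measurements.

    ``hyphae``: hypha_id, visible_length, speed (true per-hypha tip speed --
    hidden ground truth).  ``branches``: hypha_id, position_from_tip,
    branch_length plus ground-truth columns d_true (emergence distance) and
    age_true.  Reproducible from ``seed`` and the stored configuration.
    """

    hyphae: pd.DataFrame
    branches: pd.DataFrame
    params: ModelParams
    mp: MeasurementParams
    seed: int

    def write(self, out_dir: str | Path, prefix: str = "still") -> None:
        """CSV pair plus a JSON sidecar of ground truth and generator config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        observable = self.branches[["hypha_id", "position_from_tip", "branch_length"]]
        obs_h = self.hyphae[["hypha_id", "visible_length"]]
        observable.to_csv(out / f"{prefix}_branches.csv", index=False)
        obs_h.to_csv(out / f"{prefix}_hyphae.csv", index=False)
        sidecar = {
            "generator": self.params.to_dict(),
            "measurement": {"t_ramp": self.mp.t_ramp, "f0": self.mp.f0, "v_sd": self.mp.v_sd},
            "seed": self.seed,
            "truth": {
                "speed": self.hyphae["speed"].tolist(),
                "hypha_id": self.branches["hypha_id"].tolist(),
                "d_true": self.branches["d_true"].tolist(),
                "age_true": self.branches["age_true"].tolist(),
            },
        }
        (out / f"{prefix}_truth.json").write_text(json.dumps(sidecar, indent=1))


@dataclass
class Timelapse:
    """Frame series of a single simulated hypha at fixed capture cadence."""

    frames: pd.DataFrame  # frame, time, tip_position
    branches: pd.DataFrame  # frame, time, position, branch_length
    params: ModelParams
    mp: MeasurementParams
    seed: int


def generate_still_images(
    params: ModelParams,
    mp: MeasurementParams,
    n_hyphae: int,
    seed: int,
    visible_min: float = 15.0,
    visible_max: float = 45.0,
    chunk_size: int = 4096,
) -> StillImageDataset:
    """Generate a still-image dataset of ``n_hyphae`` hyphae.

    Visible lengths are uniform on [visible_min, visible_max] (the true
    experimental visible-length law is not knowable from still images alone;
    uniform keeps every trim up to visible_min feasible).  Per-hypha speeds
    are Normal(v, v_sd^2) truncated positive; the whole hypha -- parent
    travel, branch growth, distances -- scales with its own speed.
    """
    if n_hyphae < 1:
        raise ValueError("n_hyphae must be >= 1")
    if not 0 < visible_min <= visible_max:
        raise ValueError("need 0 < visible_min <= visible_max")
    root = np.random.SeedSequence(seed)
    n_chunks = (n_hyphae + chunk_size - 1) // chunk_size
    children = root.spawn(n_chunks)
    hy_rows, br_rows = [], []
    offset = 0
    for ci in range(n_chunks):
        m = min(chunk_size, n_hyphae - ci * chunk_size)
        rng = np.random.default_rng(children[ci])
        speeds = rng.normal(params.v, mp.v_sd, size=m)
        while (speeds <= 0).any():  # positive truncation by redraw
            bad = speeds <= 0
            speeds[bad] = rng.normal(params.v, mp.v_sd, size=int(bad.sum()))
        vis = rng.uniform(visible_min, visible_max, size=m)
        # grow each hypha to twice its visible length (randomised initials)
        t_end = 2.0 * vis / speeds
        rec, t_snap, X = _simulate_records(params, t_end, rng, v=speeds, n=m)
        h = rec["hypha"].astype(int)
        emerged = rec["t_emerge"] <= t_snap[h]
        in_window = rec["position"] >= (X[h] - vis[h])
        sel = emerged & in_window
        hsel = h[sel]
        age = t_snap[hsel] - rec["t_emerge"][sel]
        ell = branch_age_to_length(age, 1.0, mp) * speeds[hsel]
        hy_rows.append(
            pd.DataFrame(
                {"hypha_id": np.arange(m) + offset, "visible_length": vis, "speed": speeds}
            )
        )
        br_rows.append(
            pd.DataFrame(
                {
                    "hypha_id": hsel + offset,
                    "position_from_tip": X[hsel] - rec["position"][sel],
                    "branch_length": ell,
                    "d_true": rec["d_tb"][sel],
                    "age_true": age,
                }
            )
        )
        offset += m
    hyphae = pd.concat(hy_rows, ignore_index=True)
    branches = (
        pd.concat(br_rows, ignore_index=True)
        .sort_values(["hypha_id", "position_from_tip"], kind="stable")
        .reset_index(drop=True)
    )
    return StillImageDataset(hyphae=hyphae, branches=branches, params=params, mp=mp, seed=seed)


def generate_timelapse(
    params: ModelParams,
    mp: MeasurementParams,
    T_end: float,
    frame_interval: float = 6.0,
    seed: int = 0,
) -> Timelapse:
    """Snapshot series of one hypha at the stated capture cadence.

    Frames at t = 0, interval, ..., floor(T_end/interval)*interval; each
    frame lists the tip position and every branch emerged by that time with
    its current ramped length.
    """
    if T_end <= 0 or frame_interval <= 0:
        raise ValueError("T_end and frame_interval must be positive")
    rng = np.random.default_rng(seed)
    rec, t_snap, X = _simulate_records(params, T_end, rng, n=1)
    times = np.arange(0.0, T_end + 1e-9, frame_interval)
    frames = pd.DataFrame(
        {"frame": np.arange(len(times)), "time": times, "tip_position": params.v * times}
    )
    rows = []
    for fi, t in enumerate(times):
        sel = rec["t_emerge"] <= t
        if not sel.any():
            continue
        age = t - rec["t_emerge"][sel]
        rows.append(
            pd.DataFrame(
                {
                    "frame": fi,
                    "time": t,
                    "position": rec["position"][sel],
                    "branch_length": branch_age_to_length(age, params.v, mp),
                }
            )
        )
    branches = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["frame", "time", "position", "branch_length"])
    )
    return Timelapse(frames=frames, branches=branches, params=params, mp=mp, seed=seed)
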