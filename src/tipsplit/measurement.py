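"""Still-image measurement emulation: branch-age back-calculation and trimming.

A still image never catches a branch at the instant it emerges, so the
experimental protocol measures the new branch's length, converts it to an age
using the nascent-tip speed ramp (new branches start at roughly half the
established speed and reach full speed linearly over about ninety minutes),
and subtracts the parent tip's travel over that age to recover where the tip
was when the branch emerged.  When only the population-mean speed is known
the back-calculation smears the data, spreading the zero-distance atom into
the first few histogram bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .core import ModelParams
from .minimal_sim import TrimmedDistances

if TYPE_CHECKING:  # pragma: no cover
    from .fitting import FitResult
    from .synthetic_data import StillImageDataset

__all__ = [
    "MeasurementParams",
    "branch_length_to_age",
    "branch_age_to_length",
    "back_calculate_emergence_distance",
    "apply_trim",
    "extrapolate_mean_tb",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeasurementParams:
    """Observation-model parameters.

    t_ramp : duration of the nascent-branch speed ramp (min).
    f0 : initial speed fraction of a new branch (dimensionless, (0, 1]).
    v_sd : across-hyphae SD of the tip speed (um/min); used by the synthetic
        generator to emulate the speed variability that smears back-calculated
        distances when only the mean speed is known.
    """

    t_ramp: float = 90.0
    f0: float = 0.5
    v_sd: float = 0.075  # 15% of the default v = 0.5 um/min

    def __post_init__(self) -> None:
        if not 0 < self.f0 <= 1:
            raise ValueError("f0 must lie in (0, 1]")
        if self.t_ramp <= 0:
            raise ValueError("t_ramp must be positive")
        if self.v_sd < 0:
            raise ValueError("v_sd must be nonnegative")


def branch_age_to_length(t, v: float, mp: MeasurementParams):
    """Length of a branch of age ``t`` grown under the ramped speed profile.

    Speed ``s(u) = v (f0 + (1 - f0) u / t_ramp)`` for ``u <= t_ramp`` and
    ``v`` thereafter; the length is the exact integral.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be nonnegative")
    tr, f0 = mp.t_ramp, mp.f0
    ramp_part = v * (f0 * np.minimum(t, tr) + (1 - f0) * np.minimum(t, tr) ** 2 / (2 * tr))
    full_part = v * np.maximum(t - tr, 0.0)
    out = ramp_part + full_part
    return float(out) if out.ndim == 0 else out


def branch_length_to_age(ell, v: float, mp: MeasurementParams):
    """Invert the ramp integral: how long has a branch of length ``ell`` grown?

    Below the ramp boundary ``ell(t_ramp) = v t_ramp (1 + f0)/2`` the inverse
    is the positive root of a quadratic; beyond it the profile is linear.
    """
    ell = np.asarray(ell, dtype=float)
    if np.any(ell < 0):
        raise ValueError("branch length must be nonnegative")
    if v <= 0:
        raise ValueError("v must be positive")
    tr, f0 = mp.t_ramp, mp.f0
    ell_ramp = v * tr * (1 + f0) / 2.0
    if f0 == 1.0:
        out = ell / v
        return float(out) if out.ndim == 0 else out
    # (1-f0)/(2 tr) t^2 + f0 t - ell/v = 0
    disc = np.sqrt(f0**2 + 2.0 * (1 - f0) * ell / (v * tr))
    t_in = (disc - f0) * tr / (1 - f0)
    t_out = tr + (ell - ell_ramp) / v
    out = np.where(ell <= ell_ramp, t_in, t_out)
    return float(out) if out.ndim == 0 else out


def back_calculate_emergence_distance(D_now, ell, v: float, mp: MeasurementParams):
    """Tip-to-branch distance at emergence, from current geometry.

    ``D_now`` is the branch point's present distance from the parent tip and
    ``ell`` the branch's length.  The parent tip has travelled
    ``v * age(ell)`` since emergence; negative results are clamped to zero
    (the tip cannot have been behind the branch point at emergence -- with a
    misassumed speed such branches belong to the zero-distance peak).
    """
    D_now = np.asarray(D_now, dtype=float)
    if np.any(D_now < 0):
        raise ValueError("D_now must be nonnegative")
    age = branch_length_to_age(ell, v, mp)
    out = np.maximum(0.0, D_now - v * age)
    return float(out) if out.ndim == 0 else out


def apply_trim(
    dataset: "StillImageDataset",
    L: float,
    v_assumed: float | None = None,
    mp: MeasurementParams | None = None,
) -> TrimmedDistances:
    """Apply the trim protocol to a still-image dataset.

    Hyphae with visible length below ``L`` are discarded; for the rest only
    the segment within ``L`` of the tip is kept.  Tip-to-branch distances are
    back-calculated per branch; with ``v_assumed=None`` each hypha's true
    speed is used (which recovers the generator's ground truth exactly),
    otherwise the single assumed speed smears the data.  Branches whose
    back-calculated emergence point lies beyond the visible segment are
    dropped and counted in the log.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    mp = mp if mp is not None else dataset.mp
    hy = dataset.hyphae
    br = dataset.branches
    keep_h = hy.loc[hy["visible_length"] >= L]
    merged = br.merge(keep_h[["hypha_id", "visible_length", "speed"]], on="hypha_id", how="inner")
    merged = merged.loc[merged["position_from_tip"] <= L].sort_values(
        ["hypha_id", "position_from_tip"], kind="stable"
    )
    speeds = merged["speed"].to_numpy() if v_assumed is None else np.full(len(merged), v_assumed)
    if len(merged):
        # age at speed s of a branch of length ell equals the age at unit
        # speed of a branch of length ell/s (the ramp scales with s)
        age = branch_length_to_age(merged["branch_length"].to_numpy() / speeds, 1.0, mp)
        d = np.maximum(0.0, merged["position_from_tip"].to_numpy() - speeds * age)
    else:
        d = np.empty(0)
    beyond = d > merged["visible_length"].to_numpy() if len(merged) else np.zeros(0, bool)
    if beyond.any():
        log.info("dropped %d branches whose emergence predates the visible segment", int(beyond.sum()))
    keep = ~beyond
    h = merged["hypha_id"].to_numpy()[keep]
    tb = d[keep]
    pos = merged["position_from_tip"].to_numpy()[keep]
    if len(pos) > 1:
        same = h[1:] == h[:-1]
        bb = np.abs(pos[1:] - pos[:-1])[same]
        bbh = h[1:][same]
    else:
        bb = np.empty(0)
        bbh = np.empty(0, dtype=int)
    return TrimmedDistances(L=L, tb=tb, bb=bb, tb_hypha=h, bb_hypha=bbh, seed=dataset.seed)


def extrapolate_mean_tb(
    datasets: Mapping[float, TrimmedDistances],
    fixed: dict,
    seed: int,
    **fit_kwargs,
) -> tuple[float, "FitResult"]:
    """Estimate the true (infinite-trim) mean tip-to-branch distance.

    Fits the free model parameters jointly to the trimmed histograms at two
    or more trims, then evaluates the fitted model's untrimmed mean -- the
    quantity a finite trim can never measure directly.
    """
    from .analytic import mean_tb_untrimmed
    from .fitting import fit_parameters

    if len(datasets) < 2:
        raise ValueError("need datasets at >= 2 trims")
    samples = [datasets[L] for L in sorted(datasets)]
    result = fit_parameters(samples, fixed, seed, **fit_kwargs)
    fitted = ModelParams(
        **{
            **fixed,
            "sigma_N0": result.sigma_N0,
            "sigma_Nb": result.sigma_Nb,
            "p_split": result.p_split,
        }
    )
    return mean_tb_untrimmed(fitted), result
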