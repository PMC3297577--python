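"""Single-hypha stochastic simulator and snapshot measurement.

The underlying scheme is the discrete-time update: at each step of length
``dt`` the hypha elongates by ``v*dt``, the tip-focus grows by the factor
``exp(beta*dt)`` (or by ``beta*dt`` under the constant law), and a tip-focus
at or above ``N_min`` splits with probability ``1 - exp(-p_split*dt)``.  On a
split, nascent sizes ``N0`` and ``Nb`` are drawn from their zero-truncated
laws, the record's emergence time follows from the growth law, and the
tip-focus is decremented by ``N0`` (redrawing N0 in the vanishingly rare case
that it would exceed the current tip-focus).

Because focus growth between splits is deterministic and the per-step split
trials are Bernoulli with constant probability, the step loop can be executed
event-to-event without approximation: the number of steps to eligibility is a
deterministic ceiling and the number of further steps to the split is a
geometric variate.  This module implements that exact event-driven form,
vectorised across hyphae.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    FocusRecord,
    ModelParams,
    TruncGaussSpec,
    growth_time,
    sample_focus_size,
    solve_trunc_gauss,
)

__all__ = ["HyphaSnapshot", "TrimmedDistances", "simulate_hypha", "snapshot_measure", "collect_distances"]

_N_CAP = 1e250  # tip-focus size cap; prevents float overflow in long N_min=0 runs
_MAX_REDRAWS = 100


@dataclass
class TrimmedDistances:
    """Tip-to-branch and branch-to-branch samples under trim length ``L``."""

    L: float
    tb: np.ndarray
    bb: np.ndarray
    tb_hypha: np.ndarray | None = None
    bb_hypha: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.tb = np.asarray(self.tb, dtype=float)
        self.bb = np.asarray(self.bb, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: hypha_id, kind, distance, trim, seed."""
        tb_h = self.tb_hypha if self.tb_hypha is not None else np.zeros(len(self.tb), int)
        bb_h = self.bb_hypha if self.bb_hypha is not None else np.zeros(len(self.bb), int)
        seed = -1 if self.seed is None else self.seed
        return pd.DataFrame(
            {
                "hypha_id": np.concatenate([tb_h, bb_h]).astype(int),
                "kind": ["tip_to_branch"] * len(self.tb) + ["branch_to_branch"] * len(self.bb),
                "distance": np.concatenate([self.tb, self.bb]),
                "trim": self.L,
                "seed": seed,
            }
        )


@dataclass
class HyphaSnapshot:
    """A simulated hypha at measurement time.

    Focus records are stored as parallel arrays sorted by position; the
    ``foci`` property materialises them as :class:`FocusRecord` objects.
    Records with ``t_emerge <= t`` are emerged branches, the rest are latent
    foci (invisible to still-image measurement).
    """

    t: float
    X: float
    params: ModelParams
    position: np.ndarray
    t_split: np.ndarray
    N0_drawn: np.ndarray
    Nb_drawn: np.ndarray
    t_emerge: np.ndarray
    d_tb: np.ndarray
    N_at_split: np.ndarray = field(default=None)  # tip-focus size just before the split (diagnostic)

    @property
    def foci(self) -> list[FocusRecord]:
        return [
            FocusRecord(*vals)
            for vals in zip(
                self.position, self.t_split, self.N0_drawn, self.Nb_drawn, self.t_emerge, self.d_tb
            )
        ]


def _steps_to_eligibility(N, params: ModelParams):
    """Steps until the tip-focus is at/above N_min after within-step growth.

    The first opportunity to split is the next step (growth happens before
    the split trial), hence the result is always >= 1.
    """
    if params.N_min <= 0:
        return np.ones(len(N), dtype=np.int64)
    if params.growth_law == "linear":
        need = np.log(params.N_min / N) / (params.beta * params.dt)
    else:
        need = (params.N_min - N) / (params.beta * params.dt)
    m = np.ceil(need - 1e-12).astype(np.int64)
    return np.maximum(m, 1)


def _simulate_records(
    params: ModelParams,
    t_end,
    rng: np.random.Generator,
    v=None,
    n: int | None = None,
):
    """Vectorised event-driven simulation of ``n`` independent hyphae.

    Returns (records, t_snap, X) where records is a dict of arrays with keys
    hypha, position, t_split, N0, Nb, t_emerge, d_tb, N_at_split sorted by
    (hypha, t_split); t_snap and X are per-hypha snapshot time and tip
    position (arrays of length n).
    """
    p = params
    t_end = np.atleast_1d(np.asarray(t_end, dtype=float))
    if n is None:
        n = len(t_end)
    if len(t_end) == 1:
        t_end = np.full(n, t_end[0])
    if v is None:
        v = np.full(n, p.v)
    else:
        v = np.atleast_1d(np.asarray(v, dtype=float))
        if len(v) == 1:
            v = np.full(n, v[0])
    k_end = np.ceil(t_end / p.dt - 1e-9).astype(np.int64)

    q = -math.expm1(-p.p_split * p.dt)
    spec0 = solve_trunc_gauss(p.mu_N0, p.sigma_N0)
    specb = solve_trunc_gauss(p.mu_Nb, p.sigma_Nb)

    N = np.atleast_1d(sample_focus_size(spec0, rng, size=n)).astype(float)
    k = np.zeros(n, dtype=np.int64)
    active = k < k_end

    cols: dict[str, list[np.ndarray]] = {
        key: [] for key in ("hypha", "t_split", "N0", "Nb", "t_emerge", "d_tb", "N_at_split")
    }
    while active.any():
        idx = np.flatnonzero(active)
        Ni, ki = N[idx], k[idx]
        m = _steps_to_eligibility(Ni, p)
        g = rng.geometric(q, size=len(idx))
        ks = ki + m + g - 1
        done = ks > k_end[idx]
        if done.any():
            di = idx[done]
            k[di] = k_end[di]
            active[di] = False
        live = ~done
        if not live.any():
            continue
        li = idx[live]
        ksl = ks[live]
        steps = (ksl - ki[live]).astype(float)
        if p.growth_law == "linear":
            Na = np.minimum(Ni[live] * np.exp(p.beta * p.dt * steps), _N_CAP)
        else:
            Na = Ni[live] + p.beta * p.dt * steps
        # draw N0, redrawing where it would exceed the current tip-focus
        N0d = np.atleast_1d(sample_focus_size(spec0, rng, size=len(li))).astype(float)
        bad = N0d >= Na
        attempts = 0
        while bad.any() and attempts < _MAX_REDRAWS:
            N0d[bad] = np.atleast_1d(sample_focus_size(spec0, rng, size=int(bad.sum())))
            bad = N0d >= Na
            attempts += 1
        cancelled = bad  # redraw budget exhausted: no split this step
        Nbd = np.atleast_1d(sample_focus_size(specb, rng, size=len(li))).astype(float)
        ok = ~cancelled
        if ok.any():
            tau = growth_time(N0d[ok], Nbd[ok], p)
            ts = ksl[ok] * p.dt
            cols["hypha"].append(li[ok])
            cols["t_split"].append(ts)
            cols["N0"].append(N0d[ok])
            cols["Nb"].append(Nbd[ok])
            cols["t_emerge"].append(ts + tau)
            cols["d_tb"].append(v[li[ok]] * np.atleast_1d(tau))
            cols["N_at_split"].append(Na[ok])
        N[li] = np.where(cancelled, Na, Na - N0d)
        k[li] = ksl
        still = k[li] < k_end[li]
        active[li] = still

    if cols["hypha"]:
        rec = {key: np.concatenate(vals) for key, vals in cols.items()}
        order = np.lexsort((rec["t_split"], rec["hypha"]))
        rec = {key: val[order] for key, val in rec.items()}
    else:
        rec = {key: np.empty(0) for key in cols}
        rec["hypha"] = rec["hypha"].astype(np.int64)
    rec["position"] = v[rec["hypha"].astype(int)] * rec["t_split"] if len(rec["hypha"]) else np.empty(0)
    t_snap = k_end * p.dt
    return rec, t_snap, v * t_snap


def simulate_hypha(params: ModelParams, L: float, rng: np.random.Generator) -> HyphaSnapshot:
    """Grow one hypha to twice the trim length and return its snapshot.

    Growing to ``2L`` before measuring randomises the initial conditions so
    that the tip-anchored window ``[X - L, X]`` samples the stationary
    splitting process.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    rec, t_snap, X = _simulate_records(params, 2.0 * L / params.v, rng, n=1)
    return HyphaSnapshot(
        t=float(t_snap[0]),
        X=float(X[0]),
        params=params,
        position=rec["position"],
        t_split=rec["t_split"],
        N0_drawn=rec["N0"],
        Nb_drawn=rec["Nb"],
        t_emerge=rec["t_emerge"],
        d_tb=rec["d_tb"],
        N_at_split=rec["N_at_split"],
    )


def snapshot_measure(s: HyphaSnapshot, L: float) -> TrimmedDistances:
    """Apply the trim protocol to one snapshot.

    Only emerged branches (``t_emerge <= t``) whose branch point lies within
    ``L`` of the tip are recorded; each contributes its stored tip-to-branch
    distance, and consecutive included branches contribute a branch-to-branch
    gap.  Latent foci are invisible.  Every returned value lies in [0, L]:
    emergence before the snapshot forces ``position + d_tb <= X``.
    """
    if s.X < 2.0 * L - 1e-9:
        raise ValueError("snapshot was generated with total length < 2L")
    mask = (s.t_emerge <= s.t) & (s.position >= s.X - L)
    pos = s.position[mask]
    tb = s.d_tb[mask]
    bb = np.diff(pos)
    return TrimmedDistances(L=L, tb=tb, bb=bb)


def collect_distances(
    params: ModelParams,
    L: float,
    n_hyphae: int,
    seed: int,
    chunk_size: int = 4096,
) -> TrimmedDistances:
    """Pool trimmed distances over independent hyphae.

    Hyphae are simulated in fixed-size chunks whose seeds are spawned from a
    root ``SeedSequence``, so the pooled output is deterministic in ``seed``
    and independent of the order in which chunks are processed.
    """
    if n_hyphae < 1:
        raise ValueError("n_hyphae must be >= 1")
    root = np.random.SeedSequence(seed)
    n_chunks = (n_hyphae + chunk_size - 1) // chunk_size
    children = root.spawn(n_chunks)
    t_end = 2.0 * L / params.v
    tb_parts, bb_parts, tbh_parts, bbh_parts = [], [], [], []
    offset = 0
    for ci in range(n_chunks):
        m = min(chunk_size, n_hyphae - ci * chunk_size)
        rng = np.random.default_rng(children[ci])
        rec, t_snap, X = _simulate_records(params, t_end, rng, n=m)
        mask = (rec["t_emerge"] <= t_snap[0]) & (rec["position"] >= X[0] - L)
        h = rec["hypha"][mask].astype(int)
        pos = rec["position"][mask]
        tb_parts.append(rec["d_tb"][mask])
        tbh_parts.append(h + offset)
        if len(pos) > 1:
            same = h[1:] == h[:-1]
            bb_parts.append((pos[1:] - pos[:-1])[same])
            bbh_parts.append(h[1:][same] + offset)
        offset += m
    tb = np.concatenate(tb_parts) if tb_parts else np.empty(0)
    bb = np.concatenate(bb_parts) if bb_parts else np.empty(0)
    tbh = np.concatenate(tbh_parts) if tbh_parts else np.empty(0, dtype=int)
    bbh = np.concatenate(bbh_parts) if bbh_parts else np.empty(0, dtype=int)
    return TrimmedDistances(L=L, tb=tb, bb=bb, tb_hypha=tbh, bb_hypha=bbh, seed=seed)
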