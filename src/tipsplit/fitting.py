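"""Fit (sigma_N0, sigma_Nb, p_split) to trimmed distance histograms.

The means mu_N0, mu_Nb, the speed v, the binding parameter beta and the
critical mass N_min are fixed from independent measurements (distance data
alone cannot identify the overall v/beta scale); the free parameters are the
two size-law standard deviations and the splitting rate.  The objective is a
binned multinomial negative log-likelihood, summed over the tip-to-branch and
branch-to-branch histograms (and over trims when several datasets are fitted
jointly).  Tip-to-branch bin probabilities come from the analytic trimmed
density (noise-free); branch-to-branch probabilities come from a reference
simulation re-run with the same seed for every candidate (common random
numbers), which keeps the objective surface smooth enough for derivative-free
optimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .analytic import tb_density_trimmed
from .core import InfeasibleTruncationError, ModelParams
from .minimal_sim import TrimmedDistances, collect_distances

__all__ = ["FitResult", "histogram_objective", "fit_parameters"]

_SMOOTH = 0.5  # Dirichlet-style floor so occupied bins never get zero mass


@dataclass
class FitResult:
    """Outcome of a histogram fit."""

    sigma_N0: float
    sigma_Nb: float
    p_split: float
    N_min: float
    objective: float
    edges: list
    converged: bool
    n_evals: int
    seed: int
    message: str = ""
    restarts: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sigma_N0": self.sigma_N0,
            "sigma_Nb": self.sigma_Nb,
            "p_split": self.p_split,
            "N_min": self.N_min,
            "objective": self.objective,
            "edges": np.asarray(self.edges, dtype=float).tolist(),
            "converged": self.converged,
            "n_evals": self.n_evals,
            "seed": self.seed,
            "message": self.message,
        }


def histogram_objective(counts: np.ndarray, probs: np.ndarray) -> float:
    """Multinomial negative log-likelihood of bin counts under bin probabilities.

    Up to the count-dependent constant; permutation-invariant in the samples
    and minimised (over probability vectors) at the empirical frequencies.
    """
    counts = np.asarray(counts, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("empty histogram")
    if np.any((counts > 0) & (probs <= 0)):
        raise ValueError("zero predicted mass in an occupied bin")
    occ = counts > 0
    return float(-np.sum(counts[occ] * np.log(probs[occ])))


def _bb_probs(params: ModelParams, L: float, edges: np.ndarray, n_hyphae: int, seed: int) -> np.ndarray:
    ref = collect_distances(params, L, n_hyphae, seed)
    counts, _ = np.histogram(ref.bb, edges)
    k = len(counts)
    return (counts + _SMOOTH) / (counts.sum() + _SMOOTH * k)


def _tb_probs(params: ModelParams, L: float, edges: np.ndarray) -> np.ndarray:
    probs = tb_density_trimmed(params, L).bin_probs(edges)
    probs = np.maximum(probs, 0.0)
    probs /= probs.sum()
    k = len(probs)
    return probs * (1.0 - 1e-6) + 1e-6 / k  # floor: no occupied bin at zero mass


def fit_parameters(
    samples: TrimmedDistances | Sequence[TrimmedDistances],
    fixed: dict,
    seed: int,
    n_restarts: int = 5,
    n_bins: int = 25,
    n_hyphae_bb: int = 2000,
    maxiter: int = 70,
    free_N_min: bool = False,
) -> FitResult:
    """Derivative-free fit of the free minimal-model parameters.

    ``fixed`` must provide v, beta, mu_N0, mu_Nb (dt/growth_law optional);
    N_min is tied to mu_Nb unless ``free_N_min``.  Restarts begin from the
    best points of a fixed coarse grid; Nelder-Mead then refines in log
    space.  Deterministic given ``seed`` (one derived seed drives the
    common-random-numbers reference simulations for every candidate).
    """
    if isinstance(samples, TrimmedDistances):
        samples = [samples]
    if not samples or any(len(s.tb) + len(s.bb) == 0 for s in samples):
        raise ValueError("samples must be nonempty")
    fixed = dict(fixed)
    fixed.setdefault("N_min", fixed["mu_Nb"])
    base = ModelParams(**{**fixed, "sigma_N0": 0.0, "sigma_Nb": 0.0, "p_split": 1e-3})

    crn_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    edges_list = [np.linspace(0.0, s.L, n_bins + 1) for s in samples]
    tb_counts = [np.histogram(s.tb, e)[0] for s, e in zip(samples, edges_list)]
    bb_counts = [np.histogram(s.bb, e)[0] for s, e in zip(samples, edges_list)]

    lo = [1e-3 * fixed["mu_N0"], 1e-3 * fixed["mu_Nb"], 1e-3]
    hi = [0.9 * fixed["mu_N0"], 0.9 * fixed["mu_Nb"], 0.099 / base.dt]
    if free_N_min:
        lo.append(0.2 * fixed["mu_Nb"])
        hi.append(5.0 * fixed["mu_Nb"])
    lo, hi = np.array(lo), np.array(hi)
    n_free = len(lo)
    n_evals = 0

    def objective(logth: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        th = np.exp(logth)
        pen = 0.0
        for j in range(n_free):
            if th[j] < lo[j]:
                pen += 1e4 * (math.log(lo[j]) - logth[j])
                th[j] = lo[j]
            elif th[j] > hi[j]:
                pen += 1e4 * (logth[j] - math.log(hi[j]))
                th[j] = hi[j]
        try:
            cand = base.replace(sigma_N0=th[0], sigma_Nb=th[1], p_split=th[2])
            if free_N_min:
                cand = cand.replace(N_min=th[3])
            total = pen
            for s, e, ctb, cbb in zip(samples, edges_list, tb_counts, bb_counts):
                if ctb.sum() > 0:
                    total += histogram_objective(ctb, _tb_probs(cand, s.L, e))
                if cbb.sum() > 0:
                    total += histogram_objective(cbb, _bb_probs(cand, s.L, e, n_hyphae_bb, crn_seed))
            return total
        except (InfeasibleTruncationError, ValueError):
            return 1e12 + pen

    # fixed coarse grid of starting points
    grid = [
        np.log(([a * fixed["mu_N0"], b * fixed["mu_Nb"], p] + ([fixed["N_min"]] if free_N_min else [])))
        for a in (0.2, 0.45, 0.7)
        for b in (0.1, 0.3)
        for p in (0.05, 0.2, 0.6)
    ]
    scored = sorted(((objective(g), i) for i, g in enumerate(grid)), key=lambda t: t[0])
    starts = [grid[i] for _, i in scored[:n_restarts]]

    best = None
    restarts = []
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-3, "adaptive": True},
        )
        restarts.append({"x0": list(np.exp(x0)), "fun": float(res.fun), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    th = np.clip(np.exp(best.x), lo, hi)
    converged = any(r["success"] for r in restarts)
    return FitResult(
        sigma_N0=float(th[0]),
        sigma_Nb=float(th[1]),
        p_split=float(th[2]),
        N_min=float(th[3]) if free_N_min else float(fixed["N_min"]),
        objective=float(best.fun),
        edges=[list(e) for e in edges_list],
        converged=converged,
        n_evals=n_evals,
        seed=seed,
        message="" if converged else "no restart converged; best point returned",
        restarts=restarts,
    )
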