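"""Analytic tip-to-branch distance distributions.

With nascent size ``N0`` and branch-initiation size ``Nb`` drawn from
independent zero-truncated Gaussians, the emergence distance is

    d = (v/beta) * ln(Nb/N0)   if N0 < Nb,   else 0,

so the untrimmed law is a point mass at zero of weight ``P(N0 >= Nb)`` plus a
continuous part obtained by a change of variables,

    f(d) = g * e^{g d} * Int f_{N0}(x) * x * f_{Nb}(x e^{g d}) dx,   g = beta/v.

Under the still-image trim protocol a branch with emergence distance ``d``
remains inside the tip-anchored window of length ``L`` while the tip travels
a further ``L - d``, so snapshot sampling weights the law by ``(L - d)`` on
[0, L] (the zero atom gets weight ``L``); the observed density therefore
vanishes at ``d = L`` purely as a consequence of trimming.

All integrals use fixed Gauss-Legendre panels; an analytic branch-to-branch
density at finite splitting rate is deliberately absent (simulation only,
except for the large-rate limit in :func:`tipsplit.core.bb_distance_large_p`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .core import ModelParams, TruncGaussSpec, solve_trunc_gauss

__all__ = [
    "TbDensity",
    "TrimmedDensity",
    "tb_density_untrimmed",
    "tb_density_trimmed",
    "trim_density",
    "mean_tb_untrimmed",
    "mean_tb_trimmed",
    "mode_tb",
    "density_to_frame",
]

_GL_NODES = 250


from functools import lru_cache


@lru_cache(maxsize=16)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)


def _gl_panel(a: float, b: float, n: int = _GL_NODES):
    x, w = _leggauss(n)
    mid, half = 0.5 * (a + b), 0.5 * (b - a)
    return mid + half * x, half * w


@dataclass
class TbDensity:
    """Untrimmed law of the tip-to-branch distance.

    ``atom`` is the weight of the point mass at 0; ``pdf`` the continuous
    part; ``point_mass_at`` is set instead when both size laws are degenerate
    (the whole law is then a point mass at that distance).
    """

    atom: float
    d_max: float
    _pdf: Callable[[np.ndarray], np.ndarray] | None
    point_mass_at: float | None = None

    def pdf(self, d):
        if self._pdf is None:
            raise ValueError("degenerate distribution: point mass, no density")
        d = np.asarray(d, dtype=float)
        out = np.where((d >= 0) & (d <= self.d_max), self._pdf(np.maximum(d, 0.0)), 0.0)
        return float(out) if out.ndim == 0 else out

    def normalisation(self) -> float:
        """atom + integral of the continuous part (should be 1)."""
        if self._pdf is None:
            return 1.0
        x, w = _gl_panel(0.0, self.d_max, 2000)
        return self.atom + float(np.sum(w * self.pdf(x)))

    def mean(self) -> float:
        if self.point_mass_at is not None:
            return self.point_mass_at
        x, w = _gl_panel(0.0, self.d_max, 2000)
        return float(np.sum(w * x * self.pdf(x)))


@dataclass
class TrimmedDensity:
    """Length-bias-weighted (observed) law on [0, L]."""

    L: float
    atom: float
    _pdf: Callable[[np.ndarray], np.ndarray] | None
    point_mass_at: float | None = None

    def pdf(self, d):
        if self._pdf is None:
            raise ValueError("degenerate distribution: point mass, no density")
        d = np.asarray(d, dtype=float)
        out = np.where((d >= 0) & (d <= self.L), self._pdf(np.maximum(d, 0.0)), 0.0)
        return float(out) if out.ndim == 0 else out

    def mean(self) -> float:
        if self.point_mass_at is not None:
            return self.point_mass_at
        x, w = _gl_panel(0.0, self.L, 2000)
        return float(np.sum(w * x * self.pdf(x)))

    def bin_probs(self, edges: np.ndarray) -> np.ndarray:
        """Probability mass per bin; the zero atom is added to the first bin
        whose interval contains 0."""
        edges = np.asarray(edges, dtype=float)
        probs = np.zeros(len(edges) - 1)
        if self.point_mass_at is not None:
            j = np.searchsorted(edges, self.point_mass_at, side="right") - 1
            j = min(max(j, 0), len(probs) - 1)
            probs[j] = 1.0
            return probs
        x, w = _leggauss(24)
        a = edges[:-1]
        b = np.minimum(edges[1:], self.L)
        half = np.maximum(b - a, 0.0) / 2.0
        mid = (a + np.maximum(b, a)) / 2.0
        pts = mid[:, None] + half[:, None] * x[None, :]
        vals = self.pdf(pts.ravel()).reshape(pts.shape)
        probs = half * (vals @ w)
        j = np.searchsorted(edges, 0.0, side="right") - 1
        probs[max(j, 0)] += self.atom
        return probs


def _specs(params: ModelParams) -> tuple[TruncGaussSpec, TruncGaussSpec]:
    return (
        solve_trunc_gauss(params.mu_N0, params.sigma_N0),
        solve_trunc_gauss(params.mu_Nb, params.sigma_Nb),
    )


def tb_density_untrimmed(params: ModelParams) -> TbDensity:
    """Law of the emergence distance for independent zero-truncated draws."""
    if params.growth_law != "linear":
        raise NotImplementedError("analytic density implemented for the linear growth law")
    spec0, specb = _specs(params)
    g = params.beta / params.v

    if spec0.degenerate and specb.degenerate:
        d0 = max(0.0, math.log(specb.target_mean / spec0.target_mean) / g)
        atom = 1.0 if d0 == 0.0 else 0.0
        return TbDensity(atom=atom, d_max=d0, _pdf=None, point_mass_at=d0)

    tiny = 1e-12
    if spec0.degenerate:
        n0 = spec0.target_mean
        lo_b, hi_b = float(specb.ppf(tiny)), float(specb.ppf(1 - tiny))
        atom = float(specb.cdf(n0))
        d_max = max(math.log(max(hi_b, n0 * 1.001) / n0) / g, 1e-6)

        def pdf(d):
            y = n0 * np.exp(g * d)
            return specb.pdf(y) * y * g

        return TbDensity(atom=atom, d_max=d_max, _pdf=pdf)

    if specb.degenerate:
        nb = specb.target_mean
        lo_0 = float(spec0.ppf(tiny))
        atom = float(spec0.sf(nb))
        d_max = max(math.log(nb / max(lo_0, nb * 1e-12)) / g, 1e-6)

        def pdf(d):
            x = nb * np.exp(-g * d)
            return spec0.pdf(x) * x * g

        return TbDensity(atom=atom, d_max=d_max, _pdf=pdf)

    lo_0 = max(float(spec0.ppf(tiny)), 1e-300)
    hi_0 = float(spec0.ppf(1 - tiny))
    hi_b = float(specb.ppf(1 - tiny))
    x0, w0 = _gl_panel(max(lo_0, 0.0), hi_0)
    f0 = spec0.pdf(x0)
    atom = float(np.sum(w0 * f0 * specb.cdf(x0)))
    d_max = math.log(hi_b / lo_0) / g

    def pdf(d):
        d = np.atleast_1d(d)
        scale = np.exp(g * d)  # (m,)
        y = x0[None, :] * scale[:, None]  # (m, nodes)
        out = g * scale * np.sum(w0 * f0 * x0 * specb.pdf(y), axis=1)
        return out

    return TbDensity(atom=atom, d_max=d_max, _pdf=pdf)


def trim_density(
    pdf: Callable[[np.ndarray], np.ndarray] | None,
    atom: float,
    L: float,
    point_mass_at: float | None = None,
) -> TrimmedDensity:
    """Apply the snapshot observation weight ``(L - d)`` and renormalise.

    Generic: ``pdf`` may be any untrimmed density on d >= 0 (e.g. a uniform
    test density); the zero atom receives the full weight ``L``.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if point_mass_at is not None:
        if point_mass_at >= L:
            raise ValueError("point mass lies at/beyond the trim; nothing observable")
        return TrimmedDensity(L=L, atom=1.0 if point_mass_at == 0 else 0.0, _pdf=None, point_mass_at=point_mass_at)
    x, w = _gl_panel(0.0, L, 400)
    fx = np.asarray(pdf(x), dtype=float)
    Z = atom * L + float(np.sum(w * fx * (L - x)))
    if Z <= 0:
        raise ValueError("no observable mass below the trim length")

    def tpdf(d):
        d = np.asarray(d, dtype=float)
        return np.asarray(pdf(d), dtype=float) * (L - d) / Z

    return TrimmedDensity(L=L, atom=atom * L / Z, _pdf=tpdf)


def tb_density_trimmed(params: ModelParams, L: float) -> TrimmedDensity:
    """Observed tip-to-branch law under trim length ``L``."""
    un = tb_density_untrimmed(params)
    return trim_density(un._pdf, un.atom, L, point_mass_at=un.point_mass_at)


def mean_tb_untrimmed(params: ModelParams) -> float:
    """True (infinite-trim) mean tip-to-branch distance, zero atom included.

    Computed by product quadrature of ``(v/beta) * max(0, ln(Nb/N0))`` over
    the two size laws; decreasing in beta (exactly proportional to v/beta).
    """
    spec0, specb = _specs(params)
    scale = params.v / params.beta
    tiny = 1e-12
    if spec0.degenerate and specb.degenerate:
        return scale * max(0.0, math.log(specb.target_mean / spec0.target_mean))
    if spec0.degenerate:
        xb, wb = _gl_panel(float(specb.ppf(tiny)), float(specb.ppf(1 - tiny)), 600)
        vals = np.maximum(0.0, np.log(xb / spec0.target_mean))
        return scale * float(np.sum(wb * specb.pdf(xb) * vals))
    if specb.degenerate:
        x0, w0 = _gl_panel(max(float(spec0.ppf(tiny)), 1e-300), float(spec0.ppf(1 - tiny)), 600)
        vals = np.maximum(0.0, np.log(specb.target_mean / x0))
        return scale * float(np.sum(w0 * spec0.pdf(x0) * vals))
    x0, w0 = _gl_panel(max(float(spec0.ppf(tiny)), 1e-300), float(spec0.ppf(1 - tiny)), 600)
    xb, wb = _gl_panel(float(specb.ppf(tiny)), float(specb.ppf(1 - tiny)), 600)
    lr = np.log(xb[None, :] / x0[:, None])
    np.maximum(lr, 0.0, out=lr)
    f = (w0 * spec0.pdf(x0))[:, None] * (wb * specb.pdf(xb))[None, :]
    return scale * float(np.sum(f * lr))


def mean_tb_trimmed(params: ModelParams, L: float) -> float:
    return tb_density_trimmed(params, L).mean()


def mode_tb(params: ModelParams, L: float | None = None, grid: int = 4000) -> float:
    """Mode of the continuous part of the (optionally trimmed) density."""
    if L is None:
        den = tb_density_untrimmed(params)
        hi = den.d_max
        pdf = den.pdf
    else:
        den = tb_density_trimmed(params, L)
        hi = L
        pdf = den.pdf
    d = np.linspace(1e-9, hi, grid)
    return float(d[np.argmax(pdf(d))])


def density_to_frame(den, n: int = 512) -> pd.DataFrame:
    """Tabulate a density on a regular grid (CSV-exportable)."""
    hi = den.L if isinstance(den, TrimmedDensity) else den.d_max
    d = np.linspace(0.0, hi, n)
    return pd.DataFrame({"distance": d, "density": den.pdf(d)})
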