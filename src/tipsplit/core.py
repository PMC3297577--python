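"""Core model types and closed-form results for DivIVA-driven branching.

The model: a hyphal tip carries a cluster ("focus") of the polarity protein
DivIVA.  The tip-focus occasionally splits, leaving a small nascent focus of
size ``N0`` on the lateral membrane.  The nascent focus grows by first-order
binding of cytoplasmic DivIVA, ``dN/dt = beta * N``, until it reaches the
branch-initiation size ``Nb``, at which point a new branch emerges.  Because
the tip extends at constant speed ``v`` while the focus grows, the branch
appears a distance

    d = (v / beta) * ln(Nb / N0)          (N0 < Nb; d = 0 otherwise)

behind the tip.  ``N0`` and ``Nb`` are drawn from independent zero-truncated
Gaussians whose *truncated* means and standard deviations are the quoted
parameters.  The tip-focus itself can only split while its size is at least a
critical mass ``N_min``; in the limit of a very large splitting rate the
branch-to-branch spacing is set purely by the time to regrow from
``N_min - N0`` back to ``N_min``:

    d_bb = (v / beta) * ln(N_min / (N_min - N0)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from functools import lru_cache

import numpy as np
from scipy import optimize, special

__all__ = [
    "GROWTH_LAWS",
    "DEFAULT_SIGMA0_DISTANCE",
    "InfeasibleTruncationError",
    "ModelParams",
    "TruncGaussSpec",
    "FocusRecord",
    "beta_for_mean_distance",
    "grow_focus",
    "growth_time",
    "tip_to_branch_distance",
    "bb_distance_large_p",
    "solve_trunc_gauss",
    "sample_focus_size",
]

GROWTH_LAWS = ("linear", "constant")

#: Tip-to-branch distance (um) that the default ``beta`` produces at zero
#: size variability: (v/beta) ln(mu_Nb/mu_N0) == DEFAULT_SIGMA0_DISTANCE.
DEFAULT_SIGMA0_DISTANCE = 5.0


class InfeasibleTruncationError(ValueError):
    """No zero-truncated Gaussian attains the requested moment pair."""


def beta_for_mean_distance(v: float, mu_N0: float, mu_Nb: float, d: float) -> float:
    """Binding parameter giving tip-to-branch distance ``d`` at zero variance.

    The model is invariant under joint rescaling of (v, beta); only the ratio
    v/beta carries units of length, so beta is conveniently pinned down by a
    target distance.
    """
    if d <= 0:
        raise ValueError("target distance must be positive")
    return v * math.log(mu_Nb / mu_N0) / d


@dataclass(frozen=True)
class ModelParams:
    """Minimal-model parameters.

    Units: lengths in um, times in minutes, sizes in molecule counts.

    Attributes
    ----------
    v : tip extension speed of an established hypha (um/min).
    beta : binding parameter, effective first-order focus growth rate (1/min);
        under the linear law ``dN/dt = beta*N``; under the constant law beta
        plays the role of the constant accretion rate (molecules/min).
    mu_N0, sigma_N0 : truncated mean/SD of the nascent focus size N0.
    mu_Nb, sigma_Nb : truncated mean/SD of the branch-initiation size Nb.
    N_min : critical tip-focus mass below which splitting cannot occur.
    p_split : splitting probability per unit time once above N_min (1/min).
    dt : simulation time step (min).
    growth_law : "linear" (dN/dt = beta N) or "constant" (dN/dt = beta).
    """

    v: float = 0.5
    beta: float = field(
        default=beta_for_mean_distance(0.5, 1700.0, 10000.0, DEFAULT_SIGMA0_DISTANCE)
    )
    mu_N0: float = 1700.0
    sigma_N0: float = 1000.0
    mu_Nb: float = 10000.0
    sigma_Nb: float = 2600.0
    N_min: float = 10000.0
    p_split: float = 0.2
    dt: float = 0.1
    growth_law: str = "linear"

    def __post_init__(self) -> None:
        for name in ("v", "beta", "mu_N0", "mu_Nb", "p_split", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("sigma_N0", "sigma_Nb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.N_min < 0:
            raise ValueError("N_min must be nonnegative")
        if self.growth_law not in GROWTH_LAWS:
            raise ValueError(f"growth_law must be one of {GROWTH_LAWS}")
        # Resolution guard: per-step event probabilities must stay small for
        # the discrete-time scheme to resolve the underlying rates.
        if self.dt * self.p_split >= 0.1:
            raise ValueError("dt * p_split must be < 0.1")
        if self.growth_law == "linear" and self.dt * self.beta >= 0.1:
            raise ValueError("dt * beta must be < 0.1")

    def replace(self, **kwargs) -> "ModelParams":
        return _dc_replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "v": self.v,
            "beta": self.beta,
            "mu_N0": self.mu_N0,
            "sigma_N0": self.sigma_N0,
            "mu_Nb": self.mu_Nb,
            "sigma_Nb": self.sigma_Nb,
            "N_min": self.N_min,
            "p_split": self.p_split,
            "dt": self.dt,
            "growth_law": self.growth_law,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def wildtype(cls) -> "ModelParams":
        """Wild-type parameter set (defaults)."""
        return cls()


# ---------------------------------------------------------------------------
# zero-truncated Gaussians
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncGaussSpec:
    """A Gaussian truncated to (0, inf), parameterised by its truncated moments.

    ``target_mean``/``target_sd`` are the moments of the truncated law;
    ``underlying_mean``/``underlying_sd`` are the parameters of the full
    Gaussian before truncation.  ``target_sd == 0`` denotes a degenerate
    point mass at ``target_mean``.
    """

    target_mean: float
    target_sd: float
    underlying_mean: float
    underlying_sd: float

    @property
    def degenerate(self) -> bool:
        return self.target_sd == 0.0

    @property
    def _a(self) -> float:
        return -self.underlying_mean / self.underlying_sd

    def moments(self) -> tuple[float, float]:
        """Truncated (mean, sd) computed from the underlying parameters."""
        if self.degenerate:
            return self.target_mean, 0.0
        return _trunc_moments(self.underlying_mean, self.underlying_sd)

    def pdf(self, x):
        if self.degenerate:
            raise ValueError("degenerate spec has no density")
        x = np.asarray(x, dtype=float)
        z = (x - self.underlying_mean) / self.underlying_sd
        Q = _norm_sf(self._a)
        out = np.where(x > 0, _norm_pdf(z) / (self.underlying_sd * Q), 0.0)
        return float(out) if out.ndim == 0 else out

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.degenerate:
            out = np.where(x >= self.target_mean, 1.0, 0.0)
            return float(out) if out.ndim == 0 else out
        a = self._a
        z = (x - self.underlying_mean) / self.underlying_sd
        out = np.where(x <= 0, 0.0, (_norm_cdf(z) - _norm_cdf(a)) / _norm_sf(a))
        out = np.clip(out, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def sf(self, x):
        out = 1.0 - self.cdf(x)
        return float(out) if np.ndim(out) == 0 else out

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        if self.degenerate:
            out = np.full_like(q, self.target_mean)
            return float(out) if out.ndim == 0 else out
        a = self._a
        Fa = _norm_cdf(a)
        z = special.ndtri(Fa + q * (1.0 - Fa))
        out = self.underlying_mean + self.underlying_sd * z
        return float(out) if out.ndim == 0 else out

    def sample(self, rng: np.random.Generator, size=None):
        return sample_focus_size(self, rng, size)


_SQRT2 = math.sqrt(2.0)
_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def _norm_pdf(z):
    return np.exp(-0.5 * np.square(z)) / math.sqrt(2.0 * math.pi)


def _norm_cdf(z):
    return special.ndtr(z)


def _norm_sf(z):
    return special.ndtr(-np.asarray(z, dtype=float))


def _mills_inv(a):
    """Hazard lambda(a) = phi(a) / (1 - Phi(a)), stable for all a via erfcx."""
    return _SQRT_2_OVER_PI / special.erfcx(np.asarray(a, dtype=float) / _SQRT2)


def _trunc_moments(m: float, s: float) -> tuple[float, float]:
    """Truncated (mean, sd) of Normal(m, s^2) restricted to (0, inf)."""
    a = -m / s
    lam = float(_mills_inv(a))
    mean = m + s * lam
    var = s * s * (1.0 + a * lam - lam * lam)
    return mean, math.sqrt(max(var, 0.0))


@lru_cache(maxsize=4096)
def solve_trunc_gauss(
    target_mean: float, target_sd: float, rtol: float = 1e-9
) -> TruncGaussSpec:
    """Find the underlying Gaussian whose zero-truncated moments match targets.

    As the underlying mean goes to -inf the truncated law approaches an
    exponential-like edge law with mean/sd ratio -> 1 (from above), so the
    moment pair is attainable only for ``target_mean > target_sd``.  For
    ``target_mean/target_sd`` large (>= ~6) truncation is negligible and the
    underlying parameters coincide with the targets to high accuracy.
    """
    if not target_mean > 0:
        raise ValueError("target_mean must be positive")
    if target_sd < 0:
        raise ValueError("target_sd must be nonnegative")
    if target_sd == 0.0:
        return TruncGaussSpec(target_mean, 0.0, target_mean, 0.0)
    if target_mean / target_sd <= 1.0:
        raise InfeasibleTruncationError(
            f"mean/sd = {target_mean / target_sd:.4f} <= 1: no zero-truncated "
            "Gaussian has an sd this large relative to its mean"
        )

    def residual(x):
        m, log_s = x
        mean, sd = _trunc_moments(m, math.exp(log_s))
        return [mean / target_mean - 1.0, sd / target_sd - 1.0]

    x0 = np.array([target_mean, math.log(target_sd)])
    sol = optimize.root(residual, x0, method="hybr", tol=1e-13)
    if not sol.success or max(abs(r) for r in residual(sol.x)) > 1e-6:
        # Retry from a shifted start (helps near the feasibility boundary).
        x0b = np.array([0.1 * target_sd, math.log(1.5 * target_sd)])
        sol = optimize.root(residual, x0b, method="hybr", tol=1e-13)
    res = residual(sol.x)
    if not sol.success or max(abs(r) for r in res) > 1e-6:
        raise InfeasibleTruncationError(
            f"truncated-moment solve failed for (mean={target_mean}, "
            f"sd={target_sd}); residuals {res}"
        )
    m, log_s = sol.x
    return TruncGaussSpec(target_mean, target_sd, float(m), float(math.exp(log_s)))


def sample_focus_size(spec: TruncGaussSpec, rng: np.random.Generator, size=None):
    """Draw strictly positive focus sizes from a zero-truncated Gaussian.

    Inverse-CDF sampling through the truncnorm quantile function; exact for
    the truncated law and reproducible from the supplied generator.
    """
    if spec.degenerate:
        if size is None:
            return spec.target_mean
        return np.full(size, spec.target_mean)
    u = rng.random(size)
    x = spec.ppf(u)
    if size is None:
        return float(x)
    return x


# ---------------------------------------------------------------------------
# growth law and closed-form distances
# ---------------------------------------------------------------------------


def grow_focus(N_start, params: ModelParams, t):
    """Deterministic focus size after growing for time ``t``.

    Linear law: ``N_start * exp(beta t)``; constant law: ``N_start + beta t``.
    Focus growth is modelled deterministically: with thousands of molecules
    per focus the relative fluctuation of the accretion process is negligible.
    """
    N_start = np.asarray(N_start, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(N_start <= 0):
        raise ValueError("N_start must be strictly positive")
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if params.growth_law == "linear":
        out = N_start * np.exp(params.beta * t)
    else:
        out = N_start + params.beta * t
    return float(out) if out.ndim == 0 else out


def growth_time(N0, Nb, params: ModelParams):
    """Time for a focus to grow from ``N0`` to ``Nb`` (0 if already there)."""
    N0 = np.asarray(N0, dtype=float)
    Nb = np.asarray(Nb, dtype=float)
    if np.any(N0 <= 0) or np.any(Nb <= 0):
        raise ValueError("sizes must be strictly positive")
    if params.growth_law == "linear":
        tau = np.log(np.maximum(Nb / N0, 1.0)) / params.beta
    else:
        tau = np.maximum(Nb - N0, 0.0) / params.beta
    return float(tau) if tau.ndim == 0 else tau


def tip_to_branch_distance(N0, Nb, v: float, beta: float):
    """Distance behind the tip at which a branch emerges (Eq. 1 closed form).

    ``(v/beta) ln(Nb/N0)`` for ``N0 < Nb``; exactly 0 when the nascent focus
    is born at or above the branch-initiation size (it already has enough
    DivIVA to start outgrowth, producing the zero-distance atom).
    """
    N0 = np.asarray(N0, dtype=float)
    Nb = np.asarray(Nb, dtype=float)
    if np.any(N0 <= 0) or np.any(Nb <= 0):
        raise ValueError("focus sizes must be strictly positive")
    if v <= 0 or beta <= 0:
        raise ValueError("v and beta must be strictly positive")
    d = (v / beta) * np.log(np.maximum(Nb / N0, 1.0))
    return float(d) if d.ndim == 0 else d


def bb_distance_large_p(N0, N_min, v: float, beta: float):
    """Branch-to-branch distance in the large splitting-rate limit.

    When splitting fires as soon as the tip-focus reaches ``N_min``, each
    split drops the tip-focus to ``N_min - N0`` and the spacing is the tip
    travel while regrowing: ``(v/beta) ln(N_min/(N_min - N0))``.  Strictly
    increasing in N0; diverges as N0 -> N_min (tip-focus emptied).
    """
    N0 = np.asarray(N0, dtype=float)
    if np.any(N0 <= 0):
        raise ValueError("N0 must be strictly positive")
    if np.any(N0 >= N_min):
        raise ValueError("N0 must be smaller than N_min")
    if v <= 0 or beta <= 0:
        raise ValueError("v and beta must be strictly positive")
    d = (v / beta) * np.log(N_min / (N_min - N0))
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class FocusRecord:
    """One nascent focus created by a tip-focus split.

    ``position`` is the arc length of the focus along the parent hypha
    (0 at the hypha base), i.e. the tip position at the moment of splitting.
    ``d_tb = v * (t_emerge - t_split)`` and is 0 iff ``N0_drawn >= Nb_drawn``.
    """

    position: float
    t_split: float
    N0_drawn: float
    Nb_drawn: float
    t_emerge: float
    d_tb: float
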