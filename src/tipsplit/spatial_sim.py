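"""Full 2D colony model: curvature-gated splitting, pool accounting, nucleation.

Tips perform a persistent random walk (heading diffusion with intensity
``sigma_theta``), so memory of the growth direction is lost over a few
micrometres.  A tip-focus above the critical mass can split only when the
local path curvature, estimated over a trailing arc-length window, exceeds a
threshold; the nascent focus is placed on the outer side of the bend, where
branches are observed to emerge.  All foci (tip and latent) grow at rate
``beta = k_bind * rho`` with ``rho`` the shared cytoplasmic DivIVA density of
a well-mixed pool; DivIVA is conserved up to production.  Above a density
threshold ``rho_star`` spontaneous nucleation creates new foci anywhere on
existing hyphae at a rate rising linearly with the excess density -- the
regime reached under heavy (e.g. 25x) overexpression, which produces
branches well behind the positions tips had at induction.  Latent foci
emerge as new tips growing under the nascent-branch speed ramp.

Implementation notes.  Tips advance in lockstep with step ``dt``.  Because
every focus grows by the same factor ``exp(beta dt)`` per step, a latent
focus born at accumulated growth ``B0 = int beta dt`` emerges when the
running integral ``B`` reaches ``B0 + ln(Nb/N0)``; tracking ``B`` turns
emergence into a vectorised threshold test and makes the total latent mass
``exp(B) * sum N0_j exp(-B0_j)`` available as a running scalar.  Only the
linear growth law is supported here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .core import ModelParams, sample_focus_size, solve_trunc_gauss
from .measurement import MeasurementParams, branch_age_to_length
from .minimal_sim import TrimmedDistances

__all__ = [
    "SpatialParams",
    "Scenario",
    "TipState",
    "Colony",
    "advance_tip",
    "curvature_at_tip",
    "simulate_colony",
]


@dataclass(frozen=True)
class SpatialParams:
    """Parameters of the 2D model beyond the minimal ones.

    sigma_theta : heading-noise intensity (rad/min^0.5); the heading variance
        grows as sigma_theta^2 * t, so direction memory is lost over the
        persistence length v/sigma_theta^2 (~3 um at the defaults).
    w_curv : trailing arc-length window for curvature estimation (um).
    kappa_star : curvature threshold for splitting (1/um); 0 disables the
        gate, reducing split statistics to the minimal model.
    k_bind : per-density binding constant, beta = k_bind * rho.
    rho0 : wild-type cytoplasmic density (arbitrary density units); the
        default k_bind * rho0 reproduces the minimal model's beta.
    rho_star : nucleation density threshold.
    c_nuc : nucleation rate slope above threshold (1/(um * min * density)).
    vol_per_len : cytoplasm volume per unit hyphal length.
    production_rate : floor DivIVA synthesis per unit length (molecules/(um min)).
    overexpression_factor : production multiplier after induction.
    tip_cap : maximum number of simulated tips; beyond it new branches are
        recorded but not grown (colony truncated, flagged).
    rho_cap : ceiling on rho in the dynamic-pool regime (supply saturation).
    """

    sigma_theta: float = 0.408
    w_curv: float = 1.0
    kappa_star: float = 0.0
    k_bind: float = ModelParams().beta / 2000.0
    rho0: float = 2000.0
    rho_star: float = 4000.0
    c_nuc: float = 1e-5
    vol_per_len: float = 1.0
    production_rate: float = 50.0
    overexpression_factor: float = 25.0
    tip_cap: int = 3000
    rho_cap: float = 10000.0

    def __post_init__(self) -> None:
        for name in ("sigma_theta", "w_curv", "kappa_star", "k_bind", "rho0",
                     "rho_star", "c_nuc", "vol_per_len", "production_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def replace(self, **kw) -> "SpatialParams":
        return _dc_replace(self, **kw)


@dataclass(frozen=True)
class Scenario:
    """Expression scenario.

    ``wildtype``: balanced production holds rho at rho0 (< rho_star), so
    spontaneous nucleation never fires.  ``overexpress``: balanced until
    ``t_induce``, then production jumps to overexpression_factor times the
    balancing rate and rho evolves dynamically.  ``underexpress``: balanced
    at half rho0 (smaller beta, hence longer tip-to-branch distances).
    """

    kind: str = "wildtype"
    t_induce: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("wildtype", "overexpress", "underexpress"):
            raise ValueError("kind must be wildtype, overexpress or underexpress")


@dataclass
class TipState:
    """Vectorised tip state (equal-length arrays; one entry per tip)."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    s: np.ndarray  # arc length from the tip's own base
    N: np.ndarray  # tip-focus size
    t_birth: np.ndarray


def advance_tip(state: TipState, v_eff, sigma_theta: float, dt: float,
                rng: np.random.Generator) -> None:
    """One heading-diffusion + extension step (in place).

    Heading gets a Normal(0, sigma_theta^2 dt) increment; the tip then moves
    ``v_eff * dt`` along the new heading and its arc length grows likewise.
    """
    n = len(state.x)
    if sigma_theta > 0:
        state.theta = state.theta + rng.normal(0.0, sigma_theta * math.sqrt(dt), size=n)
    step = np.asarray(v_eff) * dt
    state.x += step * np.cos(state.theta)
    state.y += step * np.sin(state.theta)
    state.s += step


def curvature_at_tip(polyline: np.ndarray, w_curv: float) -> float:
    """Signed curvature over the trailing window of a polyline (N x 2).

    Finite difference of the segment heading across the trailing arc-length
    window: positive for a left (counter-clockwise) turn; reflecting the path
    flips the sign.  Raises if the polyline is shorter than the window
    (curvature undefined; splitting suppressed).
    """
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or polyline.shape[0] < 3:
        raise ValueError("polyline must have at least 3 vertices")
    seg = np.diff(polyline, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    if s[-1] < w_curv:
        raise ValueError("polyline arc length shorter than curvature window")
    headings = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
    # each segment heading is the tangent at the segment's arc midpoint
    mid = 0.5 * (s[:-1] + s[1:])
    i0 = int(np.searchsorted(mid, mid[-1] - w_curv, side="left"))
    i0 = min(i0, len(headings) - 2)
    ds = mid[-1] - mid[i0]
    return float((headings[-1] - headings[i0]) / ds)


class _Grow:
    """Growable float array with amortised O(1) batch append."""

    def __init__(self, dtype=float):
        self._buf = np.empty(16, dtype=dtype)
        self.n = 0

    def extend(self, vals) -> None:
        vals = np.atleast_1d(vals)
        need = self.n + len(vals)
        if need > len(self._buf):
            new = np.empty(max(need, 2 * len(self._buf)), dtype=self._buf.dtype)
            new[: self.n] = self._buf[: self.n]
            self._buf = new
        self._buf[self.n : need] = vals
        self.n = need

    @property
    def a(self) -> np.ndarray:
        return self._buf[: self.n]

    def keep(self, mask: np.ndarray) -> None:
        kept = self._buf[: self.n][mask]
        self.n = len(kept)
        self._buf[: self.n] = kept


@dataclass
class Colony:
    """Simulated colony state plus branch records and diagnostics.

    ``branch_records`` has one row per emerged branch: parent tip id,
    position on the parent (arc length from the parent's base), creation and
    emergence times, tip-to-branch distance at emergence, origin ("split" or
    "nucleation") and the spawned tip id (-1 if the tip cap prevented
    growth).
    """

    params: ModelParams
    spatial: SpatialParams
    scenario: Scenario
    tips: TipState
    t: float
    branch_records: pd.DataFrame
    total_divIVA: float
    cytoplasm: float
    rho: float
    parent: np.ndarray
    base_pos_on_parent: np.ndarray
    induction_tip_pos: np.ndarray | None
    polylines: dict
    mp: MeasurementParams
    n_nucleations: int = 0
    capped_branches: int = 0
    max_conservation_err: float = 0.0
    stalled_steps: int = 0

    @property
    def n_tips(self) -> int:
        return len(self.tips.x)

    def total_length(self) -> float:
        return float(self.tips.s.sum())

    def ramp_length(self) -> float:
        return float(branch_age_to_length(self.mp.t_ramp, self.params.v, self.mp))

    def trimmed_distances(self, L: float, min_extra: float = 0.0) -> TrimmedDistances:
        """Trim-protocol measurement over established hyphae.

        Only hyphae whose tip-anchored window (plus a randomisation margin of
        one further trim length) was laid down at full speed are measured --
        arc length >= ramp length + 2L + min_extra -- mirroring the
        experimental restriction to established hyphae.
        """
        min_len = self.ramp_length() + 2.0 * L + min_extra
        br = self.branch_records
        par = br["parent"].to_numpy()
        pos = br["position"].to_numpy()
        tem = br["t_emerge"].to_numpy()
        dtb = br["d_tb"].to_numpy()
        order = np.lexsort((pos, par))
        par, pos, tem, dtb = par[order], pos[order], tem[order], dtb[order]
        tb_parts, bb_parts, tbh, bbh = [], [], [], []
        for tid in np.flatnonzero(self.tips.s >= min_len):
            a = np.searchsorted(par, tid, side="left")
            b = np.searchsorted(par, tid, side="right")
            if b <= a:
                continue
            stip = self.tips.s[tid]
            sel = (tem[a:b] <= self.t) & (pos[a:b] >= stip - L)
            pp = pos[a:b][sel]
            if not len(pp):
                continue
            tb_parts.append(dtb[a:b][sel])
            tbh.append(np.full(len(pp), tid))
            if len(pp) > 1:
                bb_parts.append(np.diff(pp))
                bbh.append(np.full(len(pp) - 1, tid))
        tb = np.concatenate(tb_parts) if tb_parts else np.empty(0)
        bb = np.concatenate(bb_parts) if bb_parts else np.empty(0)
        return TrimmedDistances(
            L=L, tb=tb, bb=bb,
            tb_hypha=np.concatenate(tbh) if tbh else np.empty(0, dtype=int),
            bb_hypha=np.concatenate(bbh) if bbh else np.empty(0, dtype=int),
        )

    def first_offshoot_distances(self) -> np.ndarray:
        """Arc distance from each branch's base to its first own offshoot."""
        br = self.branch_records[self.branch_records["t_emerge"] <= self.t]
        first = br.groupby("parent")["position"].min()
        first = first[first.index > 0]  # the founding hypha is not a branch
        return first.to_numpy(dtype=float)

    def vertices_frame(self) -> pd.DataFrame:
        rows = []
        for tid, verts in self.polylines.items():
            arr = np.asarray(verts)
            rows.append(pd.DataFrame({"hypha_id": tid, "x": arr[:, 0], "y": arr[:, 1], "s": arr[:, 2]}))
        return pd.concat(rows, ignore_index=True)

    def events_frame(self) -> pd.DataFrame:
        return self.branch_records.copy()


def simulate_colony(
    params: ModelParams,
    spatial: SpatialParams,
    scenario: Scenario,
    T_end: float,
    seed: int,
    mp: MeasurementParams | None = None,
    polyline_stride: int = 10,
) -> Colony:
    """Grow a colony from a single spore-borne focus and record every branch."""
    if params.growth_law != "linear":
        raise NotImplementedError("the 2D model supports the linear growth law only")
    mp = mp or MeasurementParams()
    p, sp = params, spatial
    rng = np.random.default_rng(seed)
    dt = p.dt
    q = -math.expm1(-p.p_split * dt)
    spec0 = solve_trunc_gauss(p.mu_N0, p.sigma_N0)
    specb = solve_trunc_gauss(p.mu_Nb, p.sigma_Nb)

    rho = {"wildtype": sp.rho0, "overexpress": sp.rho0, "underexpress": 0.5 * sp.rho0}[scenario.kind]

    n_hist = max(int(math.ceil(sp.w_curv / (p.v * dt))) + 2, 4)
    tips = TipState(
        x=np.zeros(1), y=np.zeros(1),
        theta=np.array([rng.uniform(0.0, 2.0 * math.pi)]),
        s=np.zeros(1),
        N=np.array([float(sample_focus_size(spec0, rng))]),
        t_birth=np.zeros(1),
    )
    theta_hist = np.tile(tips.theta[:, None], (1, n_hist))
    s_hist = np.zeros((1, n_hist))
    parent = np.array([-1])
    base_pos = np.array([0.0])
    polylines: dict[int, list] = {0: [(0.0, 0.0, 0.0)]}

    # latent foci (growable columns); emergence via the integrated-growth
    # threshold B_target = B(creation) + ln(Nb/N0)
    f_parent = _Grow(np.int64)
    f_pos, f_x, f_y, f_thout = _Grow(), _Grow(), _Grow(), _Grow()
    f_N0, f_Btarget, f_B0, f_t0 = _Grow(), _Grow(), _Grow(), _Grow()
    f_origin = _Grow(np.int8)  # 0 split, 1 nucleation
    f_side, f_kappa = _Grow(), _Grow()

    rec: dict[str, list] = {k: [] for k in
                            ("parent", "position", "t_created", "t_emerge", "d_tb",
                             "origin", "tip_id", "side", "kappa_at_split")}

    B = 0.0          # integral of beta dt
    latent_S = 0.0   # sum over latent foci of N0_j * exp(-B0_j); mass = exp(B)*S
    cytoplasm = rho * sp.vol_per_len * 1e-9
    total = cytoplasm + tips.N.sum()
    dynamic_pool = False
    production = 0.0
    stalled = 0
    induction_tip_pos = None
    n_nuc = 0
    capped = 0
    max_cons = 0.0
    hist_ptr = 0
    t = 0.0
    n_steps = int(round(T_end / dt))

    for step in range(n_steps):
        n = len(tips.x)
        if scenario.kind == "overexpress" and not dynamic_pool and t >= scenario.t_induce:
            beta_now = sp.k_bind * rho
            mass_now = tips.N.sum() + math.exp(B) * latent_S
            balance = (math.exp(beta_now * dt) - 1.0) * mass_now / dt
            production = sp.overexpression_factor * max(balance, sp.production_rate * tips.s.sum())
            dynamic_pool = True
            induction_tip_pos = tips.s.copy()

        # 1. move tips (new branches obey the nascent-tip speed ramp)
        age = t - tips.t_birth
        v_eff = p.v * (mp.f0 + (1.0 - mp.f0) * np.minimum(age, mp.t_ramp) / mp.t_ramp)
        advance_tip(tips, v_eff, sp.sigma_theta, dt, rng)
        hist_ptr = (hist_ptr + 1) % n_hist
        theta_hist[:, hist_ptr] = tips.theta
        s_hist[:, hist_ptr] = tips.s
        if step % polyline_stride == 0:
            for i in range(n):
                polylines[i].append((tips.x[i], tips.y[i], tips.s[i]))

        # 2. pool + focus growth
        beta = sp.k_bind * rho
        factor = math.exp(beta * dt)
        mass = float(tips.N.sum()) + math.exp(B) * latent_S
        uptake = (factor - 1.0) * mass
        if dynamic_pool:
            prod = production * dt
            cyt_new = cytoplasm + prod - uptake
            if cyt_new < 0.0:  # pool exhausted: growth stalls this step
                uptake = cytoplasm + prod
                factor = 1.0 + uptake / mass if mass > 0 else 1.0
                cyt_new = 0.0
                stalled += 1
            cytoplasm = cyt_new
            total += prod
            vol = sp.vol_per_len * max(tips.s.sum(), 1e-9)
            rho = min(cytoplasm / vol, sp.rho_cap)
        else:
            # balanced production replaces the uptake and keeps the pool at
            # rho * volume as the colony grows; rho stays pinned
            vol = sp.vol_per_len * max(tips.s.sum(), 1e-9)
            cyt_target = rho * vol
            total += uptake + (cyt_target - cytoplasm)
            cytoplasm = cyt_target
        tips.N *= factor
        B += math.log(factor)
        cons = abs(total - (cytoplasm + tips.N.sum() + math.exp(B) * latent_S))
        max_cons = max(max_cons, cons / max(total, 1.0))

        # 3. curvature-gated splits
        oldest = (hist_ptr + 1) % n_hist
        ds = tips.s - s_hist[:, oldest]
        kappa = np.where(ds > 0, (tips.theta - theta_hist[:, oldest]) / np.where(ds > 0, ds, 1.0), 0.0)
        eligible = tips.N >= p.N_min
        if sp.kappa_star > 0:
            eligible &= (ds >= 0.999 * sp.w_curv) & (np.abs(kappa) >= sp.kappa_star)
        split_idx = np.flatnonzero(eligible & (rng.random(n) < q))
        if len(split_idx):
            N0d = np.atleast_1d(sample_focus_size(spec0, rng, size=len(split_idx))).astype(float)
            bad = N0d >= tips.N[split_idx]
            tries = 0
            while bad.any() and tries < 100:
                N0d[bad] = np.atleast_1d(sample_focus_size(spec0, rng, size=int(bad.sum())))
                bad = N0d >= tips.N[split_idx]
                tries += 1
            ok = ~bad
            si = split_idx[ok]
            if len(si):
                N0d = N0d[ok]
                Nbd = np.atleast_1d(sample_focus_size(specb, rng, size=len(si))).astype(float)
                kap = kappa[si]
                side = np.where(kap != 0, -np.sign(kap), np.where(rng.random(len(si)) < 0.5, 1.0, -1.0))
                f_parent.extend(si)
                f_pos.extend(tips.s[si])
                f_x.extend(tips.x[si])
                f_y.extend(tips.y[si])
                f_thout.extend(tips.theta[si] + side * (math.pi / 2.0))
                f_N0.extend(N0d)
                f_B0.extend(np.full(len(si), B))
                f_Btarget.extend(B + np.log(np.maximum(Nbd / N0d, 1.0)))
                f_t0.extend(np.full(len(si), t + dt))
                f_origin.extend(np.zeros(len(si), dtype=np.int8))
                f_side.extend(side)
                f_kappa.extend(kap)
                tips.N[si] -= N0d
                latent_S += float(np.sum(N0d * math.exp(-B)))

        # 4. spontaneous nucleation (density above threshold only)
        if rho > sp.rho_star and sp.c_nuc > 0:
            lam = sp.c_nuc * (rho - sp.rho_star) * tips.s.sum() * dt
            k_new = int(rng.poisson(lam))
            for _ in range(k_new):
                w = tips.s / tips.s.sum()
                i = int(rng.choice(len(tips.s), p=w))
                if cytoplasm < 2.0 * p.mu_N0:  # not enough free DivIVA for a cluster
                    break
                pos = float(rng.uniform(0.0, tips.s[i]))
                arr = np.asarray(polylines[i])
                j = min(max(int(np.searchsorted(arr[:, 2], pos)), 1), len(arr) - 1)
                frac = (pos - arr[j - 1, 2]) / max(arr[j, 2] - arr[j - 1, 2], 1e-12)
                N0 = float(sample_focus_size(spec0, rng))
                Nb = float(sample_focus_size(specb, rng))
                f_parent.extend([i])
                f_pos.extend([pos])
                f_x.extend([arr[j - 1, 0] + frac * (arr[j, 0] - arr[j - 1, 0])])
                f_y.extend([arr[j - 1, 1] + frac * (arr[j, 1] - arr[j - 1, 1])])
                f_thout.extend([rng.uniform(0.0, 2.0 * math.pi)])
                f_N0.extend([N0])
                f_B0.extend([B])
                f_Btarget.extend([B + math.log(max(Nb / N0, 1.0))])
                f_t0.extend([t + dt])
                f_origin.extend(np.ones(1, dtype=np.int8))
                f_side.extend([0.0])
                f_kappa.extend([0.0])
                latent_S += N0 * math.exp(-B)
                cytoplasm -= N0  # nucleated mass comes out of the pool
                n_nuc += 1

        # 5. emergence of latent foci into new tips
        if f_N0.n:
            ready = np.flatnonzero(B >= f_Btarget.a)
            if len(ready):
                beta_now = sp.k_bind * rho
                for j in ready:
                    pid = int(f_parent.a[j])
                    size_now = f_N0.a[j] * math.exp(B - f_B0.a[j])
                    # sub-step emergence-time correction removes dt quantisation
                    delta = (B - f_Btarget.a[j]) / beta_now if beta_now > 0 else 0.0
                    v_par = p.v * (mp.f0 + (1.0 - mp.f0) * min(t - tips.t_birth[pid], mp.t_ramp) / mp.t_ramp)
                    d_tb = max(tips.s[pid] - v_par * min(delta, dt) - f_pos.a[j], 0.0)
                    new_id = -1
                    if len(tips.x) < sp.tip_cap:
                        new_id = len(tips.x)
                        tips.x = np.append(tips.x, f_x.a[j])
                        tips.y = np.append(tips.y, f_y.a[j])
                        tips.theta = np.append(tips.theta, f_thout.a[j])
                        tips.s = np.append(tips.s, 0.0)
                        tips.N = np.append(tips.N, size_now)
                        tips.t_birth = np.append(tips.t_birth, t + dt)
                        theta_hist = np.vstack([theta_hist, np.full((1, n_hist), f_thout.a[j])])
                        s_hist = np.vstack([s_hist, np.zeros((1, n_hist))])
                        parent = np.append(parent, pid)
                        base_pos = np.append(base_pos, f_pos.a[j])
                        polylines[new_id] = [(f_x.a[j], f_y.a[j], 0.0)]
                    else:
                        capped += 1
                        cytoplasm += size_now  # unsimulated branch returns its mass
                    latent_S -= f_N0.a[j] * math.exp(-f_B0.a[j])
                    rec["parent"].append(pid)
                    rec["position"].append(float(f_pos.a[j]))
                    rec["t_created"].append(float(f_t0.a[j]))
                    rec["t_emerge"].append(t + dt)
                    rec["d_tb"].append(float(d_tb))
                    rec["origin"].append("split" if f_origin.a[j] == 0 else "nucleation")
                    rec["tip_id"].append(new_id)
                    rec["side"].append(float(f_side.a[j]))
                    rec["kappa_at_split"].append(float(f_kappa.a[j]))
                keep = B < f_Btarget.a
                for g in (f_parent, f_pos, f_x, f_y, f_thout, f_N0, f_Btarget, f_B0,
                          f_t0, f_origin, f_side, f_kappa):
                    g.keep(keep)
                # refresh the running sum (float hygiene; total is untouched:
                # emergence only moves mass between compartments)
                latent_S = float(np.sum(f_N0.a * np.exp(-f_B0.a))) if f_N0.n else 0.0
        if B > 200.0:  # rebase the growth integral to avoid exp overflow
            latent_S *= math.exp(B - 100.0)
            if f_N0.n:
                f_B0._buf[: f_B0.n] -= B - 100.0
                f_Btarget._buf[: f_Btarget.n] -= B - 100.0
            B = 100.0
        t += dt

    return Colony(
        params=p, spatial=sp, scenario=scenario, tips=tips, t=t,
        branch_records=pd.DataFrame(rec),
        total_divIVA=total, cytoplasm=cytoplasm, rho=rho,
        parent=parent, base_pos_on_parent=base_pos,
        induction_tip_pos=induction_tip_pos, polylines=polylines, mp=mp,
        n_nucleations=n_nuc, capped_branches=capped,
        max_conservation_err=max_cons, stalled_steps=stalled,
    )
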