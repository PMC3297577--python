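# Methods

## Model

### Focus growth and the tip-to-branch distance

A DivIVA focus of size `N` (molecule count) grows deterministically by
first-order binding, `dN/dt = beta * N` with `beta = k * rho` for cytoplasmic
density `rho`.  Growth is deterministic because foci contain thousands of
molecules: the relative fluctuation of the accretion process is negligible,
while the *parameters* of each focus (its birth size `N0` and its
branch-initiation size `Nb`) fluctuate between foci and carry all the
variability of the model.  A constant-accretion variant (`dN/dt = beta'`) is
available through `growth_law="constant"`; it produces qualitatively similar
distributions.

A focus born at `N0` emerges as a branch on reaching `Nb`, after time
`ln(Nb/N0)/beta`, during which the tip travels `d_tb = (v/beta) ln(Nb/N0)`.
If `N0 >= Nb` the focus branches immediately: `d_tb = 0` exactly.  These
zero-distance events form an atom in the tip-to-branch law and are the origin
of its bimodality.

### Size laws: zero-truncated Gaussians

`N0` and `Nb` are independent Gaussians truncated to `(0, inf)`; the quoted
means and SDs are the moments **of the truncated laws**.  `solve_trunc_gauss`
root-finds the underlying (untruncated) parameters whose truncated moments
match the targets, using closed-form truncated-normal moments through the
scaled complementary error function (stable for any truncation severity).
The moment pair is attainable only when mean > SD: as the underlying mean
goes to minus infinity the truncated law's mean/SD ratio tends to 1 from
above, and the solver reports an infeasible pair with a diagnostic rather
than returning a spurious root.  The truncation bound is exactly zero (open
interval): a focus cannot hold a negative number of molecules.  Sampling is
by inverse CDF, so draws are strictly positive and reproducible from a
single `numpy` Generator.

### Tip-focus splitting and the branch-to-branch distance

The tip-focus splits with constant hazard `p` per unit time, but only while
its size is at least the critical mass `N_min` (wild type: `N_min = mu_Nb`).
A split removes the nascent focus's `N0` from the tip-focus (mass
conservation; the source text states only that the tip-focus shrinks), which
can drop it below `N_min` and impose a regrowth delay — this suppresses short
branch-to-branch spacings relative to a Poisson process.  In the limit of
very large `p` the spacing is exactly the regrowth distance
`(v/beta) ln(N_min/(N_min - N0))`; with `N_min = 0` the splitting process is
Poisson along the hypha with exponential spacings of mean `v/p`.  Both limits
are verified against the simulator.  If a drawn `N0` would exceed the current
tip-focus, it is redrawn (bounded at 100 attempts, then the split is
abandoned for that step); at wild-type parameters this is vanishingly rare
because splits only occur at tip-focus sizes >= 10,000 while `N0` averages
1,700.

### Simulation scheme

The defining update is discrete-time: per step `dt`, the hypha extends by
`v*dt`, the tip-focus multiplies by `exp(beta*dt)`, and an eligible tip-focus
splits with probability `1 - exp(-p*dt)` (exact for a constant hazard, unlike
`p*dt`).  Because growth between events is deterministic and the per-step
split trials are Bernoulli, the implementation advances event-to-event
without approximation: the number of steps to eligibility is a deterministic
ceiling and the number of further steps to the split is a geometric variate.
This event-driven form is *exactly* equivalent to the step loop and is what
makes the test suite's large sample sizes cheap.  Each hypha is grown to
twice the trim length before measurement so the tip-anchored window samples
the stationary process; one snapshot is taken per hypha to avoid
within-hypha correlation.  Latent foci never split and have no dynamics of
their own in the minimal model (their emergence time follows from the growth
law at creation).

Guards: `dt*p < 0.1` and `dt*beta < 0.1` are enforced so the discrete scheme
resolves both rates; the tip-focus size is capped at 1e250 to avoid float
overflow in long `N_min = 0` runs (the cap is astronomically above any
physical size and unreachable at wild-type parameters before measurement).

### Trimming and length-biased observation

All measured hyphae are standardised to a tip-anchored window of length `L`
(shorter hyphae discarded, longer ones windowed).  A branch with emergence
distance `d` remains inside the window while the tip travels a further
`L - d`, so snapshot sampling weights the underlying law by `(L - d)` on
`[0, L]`; the zero atom gets the full weight `L`.  The observed density
therefore vanishes at `d = L` — a property of the protocol, not of the
organism.  The analytic module builds the untrimmed law by a change of
variables (atom `P(N0 >= Nb)` plus a 1-D integral over the `N0` law,
evaluated on Gauss–Legendre panels sized by 9-SD truncated supports), then
applies the trim weight and renormalises.  Trimmed analytic and simulated
histograms agree to total-variation distance < 0.02 at 10^5 samples; the
branch-to-branch law at finite `p` is left to simulation (no closed form is
attempted).

### Measurement emulation

Still images rarely catch a branch at the instant of emergence.  The
protocol measures the new branch's length, converts it to an age by
inverting the nascent-tip speed ramp — speed `v*(f0 + (1-f0) t/t_ramp)` up to
`t_ramp`, then `v`, with defaults `f0 = 0.5` and `t_ramp = 90` min — and
subtracts the parent's travel `v * age` from the branch point's current
distance to the tip.  The inverse is a closed-form quadratic root below the
ramp boundary and linear beyond it.  With each hypha's true speed the
back-calculation inverts the observation model exactly; with only the
population-mean speed it smears the data, spreading the zero atom into the
first few bins (negative back-calculated distances clamp to zero, since a
branch cannot emerge ahead of the tip).  Branches whose back-calculated
emergence lies beyond the visible segment are dropped and counted in a log.
The infinite-trim mean — the quantity no finite trim measures — is estimated
by fitting the model jointly to histograms at two or more trims and
evaluating the fitted model's untrimmed mean.

### Fitting

Free parameters are `sigma_N0`, `sigma_Nb` and `p` (the means, speed, `beta`
and `N_min` are fixed from independent measurements; distance data alone
cannot set the `v/beta` scale, and `N_min` is tied to `mu_Nb` by default with
an independent fit behind a flag).  The objective is the binned multinomial
negative log-likelihood over the tip-to-branch and branch-to-branch
histograms (default 25 bins per trim), summed across trims when fitting
jointly.  Tip-to-branch bin probabilities are analytic (noise-free);
branch-to-branch probabilities come from a 2,000-hypha reference simulation
re-run with one fixed seed for every candidate (common random numbers), which
keeps the surface smooth for Nelder–Mead in log-parameter space.  Five
restarts start from the best points of a fixed coarse grid; bounds are
enforced by clipping with a log-scale penalty, so zero-variance data drive
the SD estimates onto the lower search bound rather than crashing the
truncation solver.  On synthetic wild-type data (10^4 tip-to-branch plus
branch-to-branch distances per dataset) the median relative error of the
three parameters over 20 datasets is a few percent, well inside the 15%
acceptance band; profile deviances are chi-square(1)-scaled (Wilks).

### Full 2D model

Tips perform a persistent random walk: per step the heading gains
`Normal(0, sigma_theta^2 dt)` and the tip advances `v_eff*dt`.  The default
`sigma_theta = 0.408 rad/min^0.5` gives a persistence length
`v/sigma_theta^2 ≈ 3 um` — direction memory is lost over a few micrometres.
Splitting acquires a curvature gate: the signed curvature is the heading
difference across a trailing arc window (`w_curv = 1 um`, finite-difference
of segment headings at arc midpoints), and a tip-focus above `N_min` splits
only where `|kappa| >= kappa_star`; the nascent focus is placed on the outer
side of the bend and the eventual branch grows perpendicular to the parent
on that side (the emergence angle is not constrained by the data; a
perpendicular outer-side branch matches the observed morphology).  With
`kappa_star = 0` (the default) split statistics reduce exactly to the
minimal model; a positive threshold makes `p` an effective parameter, and a
helper fraction-passing calibration can match any target effective rate.
`kappa_star` is a free parameter, not a fitted constant — the underlying
curvature preference is taken from the biology, not modelled molecularly.

All foci share one well-mixed pool: `rho = cytoplasm / (vol_per_len * total
length)` and every focus multiplies by `exp(k*rho*dt)` per step.  The pool
is maintained on a molecule scale (`rho0 = 2000` molecules per um of hypha at
`vol_per_len = 1`), with `k` chosen so `k*rho0` equals the minimal model's
`beta`.  Two regimes: *balanced* (wild type, underexpression) where
production exactly replaces uptake and `rho` stays pinned — below the
nucleation threshold `rho_star = 4000` in the wild type, at half `rho0`
under underexpression; and *dynamic* (after overexpression induction) where
production jumps to 25x the balancing rate, `rho` evolves freely (capped at
`rho_cap`, representing supply saturation), and growth stalls gracefully if
the cytoplasm cannot cover a step's uptake.  Total DivIVA equals cytoplasm
plus focus mass to 1e-9 relative at every step (verified per step in the
tests).  Above `rho_star`, spontaneous nucleation fires as a Poisson process
with rate `c_nuc * (rho - rho_star)` per unit hyphal length, positions
uniform along existing hyphae (nucleation-born foci use the same `N0` law as
split-born ones); this reproduces the overexpression phenotype, including
branches well behind the positions tips had at induction.  Emerged foci
become new tips growing under the nascent-branch speed ramp; beyond a
configurable tip cap new branches are recorded but not grown (the colony is
flagged as truncated — the cap bounds memory and time without biasing
per-hypha statistics).

Latent-focus emergence uses the running integral `B = ∫ beta dt`: a focus
born at `B0` emerges when `B >= B0 + ln(Nb/N0)`, with a sub-step overshoot
correction so emergence distances carry no `dt` quantisation.  Trim-protocol
measurement in 2D is restricted to hyphae whose window (plus one trim length
of randomisation margin) was laid down at full speed — arc length at least
ramp length + 2L — mirroring the experimental restriction to established
hyphae; without it the speed ramp would compress early-life distances.

## Synthetic data

`generate_still_images` emulates what a microscopist measures on stills:
per hypha a visible segment length (uniform on [15, 45] um by default — the
real visible-length law is unknowable from stills, and uniform keeps every
trim up to the minimum feasible), a per-hypha tip speed (Normal around `v`,
truncated positive, default CV 15% — of the magnitude needed to produce the
observed first-bin smearing; 0 for exact-closure studies), branch positions
within the segment, and branch lengths grown under the ramp at the hypha's
own speed.  Ground truth (true speeds, emergence distances, generator config,
seed) rides along in a JSON sidecar, so generate → back-calculate → trim →
fit closes exactly when true speeds are used.  `generate_timelapse` emits
frames of one hypha every 6 minutes for testing speed estimation and
focus-origin tracing.  Not emulated: pixel images, fluorescence noise,
focus-visibility thresholds, out-of-plane curvature — so passing tests
validate the statistical pipeline, not image analysis.

## Parameter defaults

| parameter | default | units | origin |
|---|---|---|---|
| mu_N0, sigma_N0 | 1,700, 1,000 | molecules | wild-type configuration (truncated moments) |
| mu_Nb, sigma_Nb | 10,000, 2,600 | molecules | wild-type configuration (truncated moments) |
| N_min | 10,000 | molecules | tied to mu_Nb (first-offshoot data show no gap) |
| v | 0.5 | um/min | typical established-tip speed scale |
| beta | 0.1772 | 1/min | pinned so (v/beta) ln(mu_Nb/mu_N0) = 5 um; the model is invariant under joint rescaling of (v, beta), so only this ratio matters |
| p_split | 0.2 | 1/min | gives ~3 um mean branch spacing |
| dt | 0.1 | min | resolution guards dt*p, dt*beta < 0.1 |
| trim L | 15 | um | keeps both distribution width and sample size |
| t_ramp, f0 | 90 min, 0.5 | — | nascent-tip speed ramp |

The tests and the acceptance script use problem sizes chosen for desk-scale
runs on one CPU: 10^5 trimmed samples for distribution equivalence, 10^4
splits for the large-`p` limit, 20 datasets of ~10^4 distances for recovery,
and three pooled ~2,500-tip colonies for the 2D reduction.

## Known limitations

- The analytic distribution machinery covers the linear growth law; the
  constant law is simulated only.  The 2D model likewise supports the linear
  law only.
- No steric interaction between hyphae, no cross-wall placement, no nutrient
  fields, no 3D growth.
- The spontaneous-nucleation rule is the simplest threshold-linear form; the
  molecular nucleation barrier is not modelled.
- `beta`, `v`, `p` and the trim lengths are configuration, not measured
  constants; all distance statistics scale with `v/beta`, so conclusions
  about shapes and ratios are scale-free while absolute distances are only
  as good as the configured scale.
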