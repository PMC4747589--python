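# Methods

## Single-cell model

Each cell is described by linear ODEs for mRNA m and fluorescent
protein p,

    dm/dt = k_m u(t) − g_m m,      dp/dt = k_p m − g_p p,

with rates in min⁻¹ (k_m in a.u.·min⁻¹ per unit input, absorbing the
absolute stimulus scale). The drive u(t) ∈ [0,1] is the hyperosmotic
valve indicator shifted by the fluid transport delay (default 2 min,
the transit time from valve to imaging chamber in such devices) and
smoothed by a first-order lag (default time constant 2 min) standing in
for diffusion-limited medium exchange and upstream signaling. u is
discretized piecewise-constant on a 0.5-min grid; because the system is
linear and the drive piecewise-constant, the state is propagated
**exactly** segment by segment (the degenerate case g_m = g_p uses an
expm1-based branch that is numerically stable for nearly equal rates).
No generic ODE solver is involved; the test suite checks agreement with
a 0.001-min RK4 oracle to 1e-6.

Observations: y_j = p(t_j − τ)(1 + σ_mult ε₁) + σ_add ε₂ with a shared
maturation delay τ (default 6 min in the generator) and combined
additive (a.u.) + multiplicative (dimensionless) Gaussian noise, equal
for all cells. The observation variance uses the model prediction, not
the datum, keeping the likelihood well-defined at low signal.

Structural non-identifiability: (c·k_m, k_p/c) leaves p(t) unchanged
for any c > 0, so only k_mp = k_m·k_p is identifiable per cell. At the
population level the mean of ln k_p is fixed during inference (its
variance stays free) and identifiable quantities are reported through
the induced moments of ln k_mp = ln k_m + ln k_p.

## Initial conditions

Newborn cells carry no shock-induced mRNA, so m = 0 at birth. The
protein level at birth is not observed (the first two hours of newborn
trajectories are discarded by QC because bud segmentation is
unreliable). The default policy ("birth_anchor") therefore starts the
state clock at birth with (m, p) = (0, 0) and adds the unobserved
birth protein as a non-negative exponentially-decaying term
a·exp(−g_p(t − t₁)), with a anchored so the prediction matches the
first retained observation — a closed form available because the system
is linear. The simpler alternative of restarting the clock at the first
retained observation ("first_obs", also available) ignores mRNA
accumulated between birth and t₁ and measurably biased ln g_m recovery
by ≈ +0.2 log-units on synthetic studies; founders (born at t = 0) are
unaffected by the choice.

## Population model and SAEM

ln θ ~ N(μ, Σ) across cells. SAEM alternates:

* **E-step:** per cell, `mcmc_steps` Metropolis–Hastings updates of
  z_i = ln θ_i targeting p(y_i | z_i)·N(z_i; μ, Σ). Proposals are a
  full 4-D random walk shaped by the Cholesky factor of the current Σ
  (so steps move along correlated directions) with a **per-cell**
  scalar step size adapted toward 0.3 acceptance during burn-in —
  cells with informative data need far smaller steps than
  weakly-constrained ones. After burn-in, adaptation is frozen except
  for a rescue rescale when a cell's acceptance collapses below 1%.
* **SA:** sufficient statistics S₁ = E[z], S₂ = E[zzᵀ] smoothed with
  γ_k = 1 during burn-in, γ_k = 1/(k − n_burnin) afterwards.
* **M-step:** μ = S₁ (mean of ln k_p clamped), Σ from the centered
  second moment, symmetrized and eigenvalue-floored at 1e-10;
  (σ_add, σ_mult) by a joint 2-D maximum-likelihood solve on the
  current residuals, SA-smoothed on the variance scale; τ by a profile
  search over a 0–30 min grid in 1-min steps every 20 iterations.
  During burn-in the diagonal of Σ is floored at a geometrically
  decaying fraction (0.95^k) of its initial value to prevent premature
  variance collapse.

Defaults — 250 burn-in + 250 SA iterations, 5 MH steps per cell per
iteration — were chosen for estimator accuracy: shorter chains visibly
attenuate the recovered cross-correlations (the E-step lags the
shrinking population distribution). A 200-cell fit takes ~20 s on one
CPU. `check_convergence` reports the relative drift of every tracked
scalar over a trailing window (default tolerance 2%).

The naive baseline fits each cell's four log-parameters independently
by Nelder-Mead (τ and the noise strengths frozen at values from a
multi-start fit of the population median trajectory; ±6 log-unit box
around the search center; 3 restarts) and pools the estimates into an
empirical mean/covariance. MAP estimation maximizes
loglik + log p(θ | μ, Σ) (including the log-normal Jacobian) over log
space, multi-starting from the prior mean and two prior draws.
Shrinkage per log-parameter is 1 − var(MAP)/Σ_kk.

## Synthetic studies

The generator emulates a 10-h experiment: fluorescence every 6 min,
8-min shocks every 60 min from t = 30 min, ~300 cells of which 60 are
founders (born at t = 0) and the rest arise from a branching division
process (division intervals ~N(100, 15²) min, floored at 30 min), so
late-born cells have short observation windows as in real data.
Daughters inherit their mother's protein level at birth and start with
m = 0. Default population: log-means ln(5.0, 0.12, 1.0, 0.008) —
mRNA half-life ≈ 6 min under stress, translation rate fixed at the
literature scale, protein decay = dilution at a ~90-min doubling time —
with log-SDs (0.40, 0.30, 0.40, 0.25), corr(ln k_m, ln k_p) = 0.5, and
cross-covariances chosen so corr(ln k_mp, ln g_m) = 0.85 exactly, plus
mild (0.2–0.3) couplings to ln g_p. Noise: σ_add = 5 a.u.,
σ_mult = 0.1.

Planted structure, all configurable:

* **Lineage:** daughter log-parameters are an AR(1)-style mixture,
  z_d = μ + ρ(z_m − μ) + √(1−ρ²)·fresh, default ρ = 0.25 — the
  implied closeness 1 − √(1−ρ) ≈ 13% matches the mild inheritance
  effects such experiments report.
* **Shock gain:** a per-cell latent log-normal gain (SD 0.15) shifts
  ln k_m (weight 1.0) and ln g_m (weight 0.6) and generates the
  `perceived_shock` feature (base relative volume drop 0.25, 10%
  measurement noise) — cells hit harder produce more and turn over
  mRNA faster.
* **Features:** `division_rate` = g_p/ln 2·(1 + 5% noise);
  `mean_density` and `mean_size` drawn with rank correlations 0.35 and
  0.30 to ln k_mp; `mean_age` uncoupled by default.

What the generator does **not** emulate: intrinsic reaction noise,
photobleaching, volume dynamics (the perceived-shock feature is
generated from the latent gain rather than from simulated volume
traces; `analysis.perceived_shock` still accepts real volume/size
traces), spatially explicit crowding, segmentation/tracking errors, and
death or dropout. Passing tests therefore demonstrate correctness of
the inference machinery under the model's own assumptions plus the
listed extrinsic-structure features — not robustness to every artifact
of real microscopy data.

## Quality control

Cells observed less than 5 h are dropped. For cells born after t = 0,
samples within the first 2 h after birth are discarded (boundary sample
kept). Lineage and feature tables are subset so no row references a
removed cell.

## Validation metrics

* **Population envelope:** n (default 10000) parameter draws simulated
  over the full horizon from (m, p) = (0, 0) — virtual cells span the
  whole experiment, unlike real cells — with time-wise median and
  2.5/97.5% quantiles; coverage is the fraction of data points inside
  the band (times matched to the nearest frame).
* **Fit error:** mean over cells and time points of |ŷ − y|/y_ref,
  y_ref the cell's time-averaged fluorescence floored at 5% of the
  peak of the population median curve (the floor prevents blow-up for
  near-dark cells), reported in percent.
* **Robustness:** seeded subsampling to {32, 64, 128, all} cells and/or
  truncation to {5, 7, 10} h, refit, scored by μ-recovery error against
  ground truth and envelope coverage on the held-out full study.

## Inheritance test

Pair distance per parameter: |ln θ_daughter − ln θ_mother|. The
observed statistic is the mean over all available mother/daughter (MD)
pairs; the null reference is built from `n_boot` random *rematchings* —
permutations of the daughters across the mothers, with any assignment
pairing a mother to her own daughter rejected and redrawn — so every
null set is a full non-related (nMD) matching with the same structure
as the observed one (each mother and each daughter used exactly once).
The one-sided p-value (add-one corrected) is the fraction of null
matchings at least as close as the observed MD matching. This
permutation construction is exactly calibrated when daughters are
exchangeable across mothers. Two variants were measured and rejected:
resampling small (40-pair) subsets on both sides (subsample variance
swamps both the null centering and the signal) and with-replacement
nMD sets (slightly over-dispersed relative to the matched observed
statistic, leaving null p-values mildly non-uniform).
Closeness% = 100(1 − mean(MD)/mean(nMD)) with mean(nMD) over every
valid non-related pairing.

## Numerical choices and edge cases

* All randomness flows through `numpy.random.Generator` objects seeded
  from a single integer; every fit is bit-reproducible given its seed.
* Log-parameters are clipped to ±40 before exponentiation in the
  vectorized likelihood; non-finite likelihood contributions map to
  −1e12 rather than NaN so optimizers and MH steps behave.
* PCA is computed on standardized log-parameters; rank-deficient
  directions get zero variance fraction and fractions are renormalized
  to sum to 1.
* Spearman correlations drop missing entries pairwise; constant columns
  report NaN rather than raising.
* The 95% confidence-ellipsoid volume is (π²/2)·r⁴·√det Σ with r² the
  0.95 quantile of χ²(4); the structure metric is the mean |Σ_ij/μ_iμ_j|
  over i ≠ j on log-scale moments (the log-scale choice is deliberate:
  the distributions being compared live in log space).

## Known limitations

* τ is estimated on a 1-min grid, not continuously; studies whose true
  delay falls between grid points resolve to the nearest minute.
* The SAEM error-model update uses residuals at the current MCMC draws;
  at moderate cell counts this can leave σ_mult a few percent above
  truth early in the run (it converges with the chain).
* k_m and k_p variances are reported as fitted but are only weakly
  constrained individually; trust the k_mp view.
* The naive baseline's τ/noise pre-fit uses the median trajectory,
  which underestimates noise strengths by construction (medians are
  smooth); this mirrors the baseline's character rather than a defect
  of the package.
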