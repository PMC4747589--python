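# mecell

Mixed-effects inference of single-cell gene-expression parameters from
time-lapse fluorescence trajectories.

## The problem

Isogenic cells respond very differently to the same stimulus. When
budding yeast carrying a stress-inducible fluorescent reporter (e.g.
yECitrine driven by the osmoresponsive pSTL1 promoter) are exposed to
repeated hyperosmotic shocks in a microfluidic device, each cell traces
its own fluorescence trajectory. Fitting one "mean-cell" model to the
averaged data misrepresents the population; fitting each cell alone
over-fits noisy, weakly-informative single trajectories. `mecell`
implements the middle road: a **nonlinear mixed-effects (ME) model** in
which every cell has its own kinetic parameters, drawn from a joint
population distribution that is estimated from all cells at once.

## The model

Per cell, a standard two-stage gene-expression model driven by the
transcription-factor activity u(t) (the valve schedule shifted by the
fluid transport delay and passed through a first-order lag):

    dm/dt = k_m u(t) − g_m m        (mRNA)
    dp/dt = k_p m    − g_p p        (protein)

Fluorescence observations are delayed by the maturation time τ and
carry combined noise: y_j = p(t_j − τ)(1 + σ_mult ε₁) + σ_add ε₂.
Across the population, θ = (k_m, g_m, k_p, g_p) is log-normal:
ln θ ~ N(μ, Σ). Only the product k_mp = k_m·k_p is identifiable from a
single cell's fluorescence, so inference fixes the mean of ln k_p and
reports the induced moments of ln k_mp.

Estimation is by **SAEM** (stochastic approximation EM, written from
scratch): Metropolis–Hastings updates of each cell's log-parameters,
stochastic-approximation smoothing of the sufficient statistics, and
closed-form M-steps, with the error strengths fitted by a residual
maximum-likelihood solve and τ by periodic profile search. Per-cell
parameters follow by MAP estimation under the fitted population prior.
A synthetic-data generator reproduces the statistical structure of such
experiments (staggered births, lineage-correlated parameters, features
coupled to parameters), so the whole pipeline is testable end to end
with known ground truth.

## Worked example

```python
import numpy as np
from mecell import (StudyConfig, generate_study, apply_qc_filters,
                    fit_saem, SAEMConfig)

config = StudyConfig(n_cells=100, n_founders=40,
                     shock_gain_sd=0.0, inheritance_rho=0.0)
study = apply_qc_filters(generate_study(config, rng=2))
pop, trace = fit_saem(study, config.build_input(), SAEMConfig(seed=2))

print(np.round(pop.mu, 2))                          # [ 1.55 -2.24  0.   -4.8 ]
print(round(pop.tau_min))                           # 5
print(round(pop.kmp_view()["corr_ln_kmp_ln_g_m"], 2))  # 0.77
```

The generating population has log-means (1.61, −2.12, 0, −4.83), a
6-min maturation delay, and corr(ln k_mp, ln g_m) = 0.85: at 100 cells
the fit recovers the free log-means within ~6%, the delay to within one
step of its 1-min search grid, and most of the planted
production/turnover correlation (recovery tightens with cell count —
the 200-cell checks in `tests/test_acceptance.py` land within a few
percent).
`examples/` contains four narrative scripts — study generation, SAEM vs
the naive per-cell baseline, MAP estimation + population validation,
and the inheritance/feature analyses — each printing the numbers it
computes with a line on what they mean.

The naive baseline (independent per-cell maximum likelihood, then
pooling) is included deliberately: its pooled covariance is inflated by
estimation noise (95%-ellipsoid volume typically an order of magnitude
above SAEM's), and resampling it fails to reproduce the population
band — the central argument for the mixed-effects route.

## Command line

A thin CLI wraps the pipeline stages:

```bash
mecell simulate --seed 1 --out demo
mecell run-all  --seed 1 --out demo
```

Stages: `simulate | qc | fit-naive | fit-saem | map | validate |
analyze | inherit | run-all`, configured via `--config config.yaml`.

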