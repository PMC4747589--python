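"""Fit the mixed-effects population model by SAEM and compare with the
naive per-cell approach.

The naive route fits each cell independently and pools the estimates;
weakly identified directions inflate its covariance.  SAEM fits all
cells jointly and recovers a compact, structured distribution.
"""

import numpy as np

from mecell import SAEMConfig, StudyConfig, apply_qc_filters, fit_saem, generate_study
from mecell.naive import fit_study_naive
from mecell.population import dispersion_metrics

config = StudyConfig(n_cells=100, n_founders=40, shock_gain_sd=0.0,
                     inheritance_rho=0.0)
study = apply_qc_filters(generate_study(config, rng=2))
input_signal = config.build_input()

pop_saem, trace = fit_saem(study, input_signal, SAEMConfig(seed=2))
naive = fit_study_naive(study, input_signal, rng=2)

truth = study.truth_population
print("log-mean recovery (truth -> SAEM):")
for i, name in enumerate(("ln k_m", "ln g_m", "ln k_p", "ln g_p")):
    print(f"  {name:8s} {truth.mu[i]: .3f} -> {pop_saem.mu[i]: .3f}")
print(f"delay tau: truth {truth.tau_min:.0f} min -> fitted {pop_saem.tau_min:.0f} min")
print(f"corr(ln k_mp, ln g_m): truth "
      f"{truth.kmp_view()['corr_ln_kmp_ln_g_m']:.2f} -> fitted "
      f"{pop_saem.kmp_view()['corr_ln_kmp_ln_g_m']:.2f}")

_, vol_saem = dispersion_metrics(pop_saem)
_, vol_naive = dispersion_metrics(naive.pooled)
print(f"95% ellipsoid volume: SAEM {vol_saem:.2f}, naive {vol_naive:.1f}")
# the naive volume is typically an order of magnitude larger: per-cell
# estimation noise masquerades as biological variability.
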