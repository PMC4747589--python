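"""Downstream analyses: parameter-feature correlations, PCA ranking and
mother/daughter inheritance.

Uses the generator's ground-truth parameters directly so the statistics
are exact; after inference the same functions run on MAP estimates.
"""

import numpy as np

from mecell import StudyConfig, apply_qc_filters, generate_study
from mecell.analysis import (correlate_features, inheritance_test,
                             md_feature_comparison, pca_rank)

study = apply_qc_filters(generate_study(StudyConfig(), rng=4))
log_params = np.log(study.truth_params[["k_mp", "g_m", "g_p"]]).rename(
    columns=lambda c: "ln_" + c)

rho, pval = correlate_features(log_params, study.features)
print("Spearman correlations (parameters x features):")
print(rho.round(2))
# division_rate tracks g_p (protein decay is dilution by growth);
# perceived_shock couples to k_mp and g_m via the per-cell shock gain.

summary = pca_rank(log_params, study.features)
print("\nPCA variance fractions:", summary.variance_fractions.round(3))
print("feature ranking (variance-weighted |rho| with the PCs):")
print(summary.feature_scores.sort_values(ascending=False).round(3))

report = inheritance_test(study.truth_params[["k_mp", "g_m", "g_p"]],
                          study.lineage, n_boot=50000, rng=4)
print("\nmother/daughter inheritance (distance |ln theta_d - ln theta_m|):")
print(report.per_parameter.round(4))
# closeness > 0 with small p: daughters are parametrically closer to
# their own mother than to another mother's daughter.

md = md_feature_comparison(study.features, study.lineage, "perceived_shock")
print(f"\ndaughter-vs-mother perceived shock: "
      f"{100 * md['mean_relative_difference']:+.1f}% "
      f"(rank correlation {md['spearman_rho']:.2f})")
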