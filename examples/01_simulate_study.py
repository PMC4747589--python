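"""Generate a synthetic repeated-shock study and look at its structure.

Builds a 10-h experiment: ~300 yeast cells with staggered births, 8-min
hyperosmotic shocks every hour, fluorescence sampled every 6 min, and
log-normally distributed kinetic parameters with planted correlations.
"""

import numpy as np

from mecell import StudyConfig, apply_qc_filters, generate_study

config = StudyConfig()  # default study conditions
study = generate_study(config, rng=1)
print(f"generated {len(study)} cells, {len(study.lineage)} mother/daughter links")

qc = apply_qc_filters(study)
print(f"after QC (>=5 h observed, first 2 h of newborns dropped): {len(qc)} cells")

lt = np.log(study.truth_params)
corr = np.corrcoef(lt["k_mp"], lt["g_m"])[0, 1]
print(f"planted corr(ln k_mp, ln g_m) realized in this draw: {corr:.3f}")
# ~0.85: cells that produce protein faster also degrade mRNA faster —
# the joint-regulation signature the inference must recover.

traj = qc.trajectories[0]
print(f"cell {traj.cell_id}: {len(traj.times)} samples, "
      f"peak fluorescence {traj.values.max():.0f} a.u.")
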