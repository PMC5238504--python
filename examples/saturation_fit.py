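"""Saturation binding: generate a synthetic [3H]NMS experiment and fit it.

Generates three independent saturation experiments (triplicate wells,
tracer 32 pM - 1 nM, 3% noise) for the wild-type M2 receptor, subtracts
nonspecific binding and fits the one-site isotherm Y = B_MAX*X/(K_D+X)
per experiment.
"""

import numpy as np

from tandemsite import AssayDesign, TABLE_PRESETS, fit_saturation, gen_saturation

truth = TABLE_PRESETS["M2_wt"]
design = AssayDesign(n_experiments=3, noise_cv=0.03, rng_seed=1)
wells = gen_saturation(truth, design)

print(f"ground truth: pK_D = {truth.pK_D}, B_MAX = {truth.B_MAX}")
pkds = []
for exp_id, grp in wells.groupby("experiment_id"):
    fit = fit_saturation(grp)
    pkds.append(fit.pK_D)
    print(f"experiment {exp_id}: pK_D = {fit.pK_D:.3f} "
          f"(SE {fit.stderr_pK_D:.3f}), B_MAX = {fit.B_MAX:.0f}")
mean, sem = np.mean(pkds), np.std(pkds, ddof=1) / np.sqrt(len(pkds))
print(f"mean pK_D = {mean:.2f} +/- {sem:.2f} (SEM, n={len(pkds)})")
print("pK_D is the negative log10 of the tracer's equilibrium dissociation")
print("constant; recovering the ground truth within the SEM shows the")
print("fit is unbiased at this noise level.")
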