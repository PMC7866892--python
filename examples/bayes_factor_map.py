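"""Voxelwise Bayes-factor t-tests on a simulated subject stack.

Builds a small synthetic group study (spherical activations, Gaussian
noise), runs the one-sample BF10 test at every voxel under an adjusted
Cauchy prior and under the conventional default scale .707, thresholds at
BF >= 3, and compares both with the Bonferroni-FWE frequentist baseline.
"""

from bfmap import (
    CauchyPrior,
    SimulationSpec,
    add_noise,
    bf_map,
    fpr_hr,
    fwe_threshold,
    make_truth,
    solve_scale,
    t_map,
    threshold_bf,
)

spec = SimulationSpec(shape=(24, 24, 18), R=0.03, signal=1.0, noise_sd=0.5)
truth = make_truth(spec)
stack = add_noise(truth, n=16, noise_sd=spec.noise_sd, seed=11)
print(f"{int(truth.truth_mask.sum())} truly active voxels "
      f"of {truth.truth_mask.size} ({truth.achieved_R:.2%})")

# Adjusted prior: the a priori information is the generating model itself
X = (spec.signal / spec.noise_sd) * spec.R
adjusted = CauchyPrior(solve_scale(X, 0.95))
print(f"adjusted prior scale sigma = {adjusted.sigma:.4f} (P = 95%)")

for label, prior in [("adjusted", adjusted), ("default .707", CauchyPrior(0.707))]:
    detected = threshold_bf(bf_map(stack, prior), cutoff=3.0)
    res = fpr_hr(detected, truth.truth_mask)
    print(f"Bayes ({label:13s}): {res.n_noise_positive:4d} detected, "
          f"FPR = {res.fpr:.3f}, HR = {res.hr:.3f}")

freq = fwe_threshold(t_map(stack), alpha=0.05)
res = fpr_hr(freq, truth.truth_mask)
print(f"frequentist FWE      : {res.n_noise_positive:4d} detected, "
      f"FPR = {res.fpr:.3f}, HR = {res.hr:.3f}")
# The Bayes-factor tests recover far more of the true activation (higher
# hit rate) while the false-discovery proportion stays small; Bonferroni
# FWE is the most conservative.
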