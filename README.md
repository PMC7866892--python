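# bfmap

Voxelwise Bayes-factor second-level fMRI analysis with Cauchy priors
adjusted from a priori information.

## The problem

Group-level ("second-level") fMRI inference asks, voxel by voxel, whether
per-subject contrast values share a nonzero mean.  The Bayesian version of
the one-sample t-test answers with a Bayes factor
BF₁₀ = P(data | H₁) / P(data | H₀), where H₁ places a Cauchy(0, σ) prior on
the standardized effect size δ and H₀ fixes δ = 0.  BF₁₀ ≥ 3 is the usual
"positive evidence" decision threshold.  The catch: BF₁₀ is sensitive to
the prior scale σ, and the conventional default σ = 1/√2 ≈ .707 ignores
everything already known about the effect under study.

`bfmap` implements a principled alternative: elicit σ from what relevant
earlier studies (typically an image-based meta-analysis) report —

* **C**, the contrast: difference between mean activity of significant and
  non-significant voxels in the reference map;
* **N**, the noise strength: standard deviation of voxel activity;
* **R**, the proportion of voxels that were significant.

The expected standardized effect is **X = (C/N)·R**, and σ is chosen so
the prior's cumulative mass below X equals a target percentile P:

    P = F_Cauchy(X; 0, σ)   ⟺   σ = X / tan(π(P − ½))

A stricter P (e.g. 95% instead of 80%) concentrates the prior at zero and
makes the downstream test more selective.

The package also ships the machinery to evaluate such analyses: a
synthetic benchmark (sphere-shaped activations plus Gaussian noise),
false-positive-rate / hit-rate scoring against known truth, a Dice-type
overlap index for comparisons against reference maps, a
number-of-tests-corrected default prior, and a Bonferroni voxelwise-FWE
frequentist baseline.

## Worked example

```python
from bfmap import PriorInfo, adjust_prior

# Working-memory meta-analysis: C = .55, N = .33, R = 12.92%
info = PriorInfo(C=0.55, N=0.33, R=0.1292)
for P in (0.80, 0.85, 0.90, 0.95):
    print(f"P = {P:.0%}: sigma = {adjust_prior(info, P=P).sigma:.4f}")
```

prints

```
P = 80%: sigma = 0.1564
P = 85%: sigma = 0.1097
P = 90%: sigma = 0.0700
P = 95%: sigma = 0.0341
```

— the prior scale shrinks as more of its mass is pinned below the expected
effect X = (.55/.33)·.1292 ≈ .215.  Applying such priors voxelwise
(`examples/bayes_factor_map.py`, a 24×24×18 synthetic study with 3% true
activation, n = 16, noise SD .5) gives

```
Bayes (adjusted     ):  317 detected, FPR = 0.019, HR = 1.000
Bayes (default .707 ):  510 detected, FPR = 0.390, HR = 1.000
frequentist FWE      :  265 detected, FPR = 0.000, HR = 0.852
```

The adjusted prior keeps essentially all true activation (hit rate 1.0)
with a small false-discovery proportion, where the unadjusted default
floods the map with false positives and Bonferroni FWE misses 15% of the
real signal.

More narrative scripts live in `examples/`:

| script | capability |
| --- | --- |
| `adjust_prior_from_meta.py` | σ from direct C/N/R and from a reference map |
| `bayes_factor_map.py` | voxelwise BF maps, thresholding, baselines |
| `simulation_study.py` | condition-grid evaluation (FPR/HR per method) |
| `overlap_comparison.py` | Dice-type overlap index between binary maps |

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
bfmap adjust-prior --c 1.0 --n 0.5 --r 0.016 --p 0.95 --out-json prior.json
bfmap bf-map --input subj_4d.nii.gz --prior-json prior.json --threshold 3 --out-dir out/
bfmap freq-map --input subj_4d.nii.gz --alpha 0.05 --out-dir out/
bfmap simulate --r 0.008 --n 16 --seed 1 --out-dir sim/
bfmap run-grid --config grid.json --out results.csv
bfmap evaluate --detected out/significant.nii.gz --truth sim/truth_mask.nii.gz
bfmap overlap --original a.nii.gz --target b.nii.gz
bfmap run-pipeline --config run.yaml
```

All volumes are NIfTI-1; masks treat any nonzero voxel as in-mask; affines
are passed through untouched.

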