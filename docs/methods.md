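# Methods

## Model

At each voxel the per-subject contrast values x₁…xₙ are modeled as
xᵢ ~ Normal(μ, s²) with standardized effect δ = μ/s.  Two hypotheses are
compared: H₀: δ = 0 and H₁: δ ~ Cauchy(x₀ = 0, σ).  With the Jeffreys
prior on s², the marginal likelihood under either hypothesis depends on
the data only through the t statistic and n, and the Bayes factor is the
one-dimensional integral

    BF₁₀(t, n, σ) = ∫₀^∞ (1+ng)^(−1/2) (1 + t²/((1+ng)ν))^(−(ν+1)/2) π(g) dg
                    ───────────────────────────────────────────────────────
                    (1 + t²/ν)^(−(ν+1)/2)

with ν = n − 1 and π(g) the InverseGamma(1/2, σ²/2) density — the
scale-mixture representation of the Cauchy prior (δ | g ~ Normal(0, g)).
Voxels are tested independently with a single global σ; the test is
two-sided by default (H₁ is "some nonzero effect").  A one-sided variant
with a half-Cauchy prior is exposed (`sides="greater"/"less"`), computed
by adaptive quadrature of the noncentral-t density against the folded
prior; it is a scalar path, not used in map-scale runs by default.

## Prior-scale elicitation

The a priori information is three numbers from relevant earlier work,
normally an image-based meta-analysis of the same kind of contrast:

| symbol | meaning | units | estimator |
| --- | --- | --- | --- |
| C | contrast | image units | mean(significant voxels) − mean(non-significant voxels) |
| N | noise strength | image units | sample SD of activity over all analyzed voxels |
| R | true-positive proportion | — | n_sig / (n_sig + n_nonsig), within the analysis mask |

The expected standardized effect is X = (C/N)·R, and σ solves
F_Cauchy(X; 0, σ) = P, i.e. σ = X / tan(π(P − ½)).  P ∈ (0.5, 1) is the
analyst's stringency dial (no automatic choice is attempted): the larger
the P, the narrower the prior and the fewer voxels that clear the BF ≥ 3
threshold.  The closed form is verified at call time against a bracketing
root-finder (1e−10 relative agreement), and a plain bisection solver is
retained as an independent slow path.

Estimator conventions worth stating explicitly:

* C is a **difference** of means.  (A ratio formulation also circulates,
  but it is undefined when the non-significant mean is ≈ 0 — e.g. on a
  two-valued reference map — and the standard worked values, such as
  C = .61 − .06 = .55, are differences; the difference is what this
  package computes.)
* N uses the sample SD (n − 1 denominator).  By default it is taken over
  all in-mask voxels; `noise_estimator="sig"`/`"nonsig"` restrict it to
  either subset, since a reference map's whole-image SD and the noise SD
  of a generating model are not the same estimator.
* R is defined against the analysis mask; out-of-mask voxels never enter.
* C ≤ 0 yields X ≤ 0, for which no positive σ exists at P > .5; this
  raises a domain error telling the user to re-orient the contrast rather
  than silently taking |C|.

## Numerical evaluation of BF₁₀

The g-integral is evaluated on z = log g with a composite Gauss–Legendre
rule: panels of width 2, 8 nodes per panel, spanning
[log σ² − 12, log max(σ², 1, t_cap²/n) + 40] with t_cap = 10⁴.  The node
set depends only on (n, σ) — never on the observed t — so a whole-map
evaluation and a single-voxel call follow bit-identical floating paths.
The integrand is accumulated in log space (log-sum-exp when the direct
product could overflow, i.e. |t| extremely large), so the result never
degenerates to 0 or ∞ for any representable input.  Accuracy is ~1e−9
relative across the practically reachable range, verified in the test
suite against two independent quadratures: an adaptive high-precision
rule in g-space (mpmath, 40 digits) and an adaptive rule in δ-space using
the noncentral-t density.  Known behavior at the edges: BF₁₀ → 1 as
σ → 0 (prior collapses onto the null) and BF₁₀ → 0 as σ → ∞
(Bartlett's phenomenon); both are asserted numerically.

Zero-variance voxels (possible in masked real data, probability zero
under the noise model) are excluded from t and BF maps with a warning and
carry NaN, the same missing-value convention used for out-of-mask voxels
in every emitted map.

## Baselines

**Corrected default prior.**  The comparison literature corrects the
default scale σ₀ = 1/√2 for the number of simultaneous tests without
stating a formula, so the rule here is explicitly pluggable and recorded
by name in run metadata.  The default rule is σ(m) = σ₀·√m
("sqrt-ntests"): widening the prior raises the per-voxel evidence bar as
the test count m grows, and this rate reproduces the stringency ordering
observed across methods (frequentist FWE ⊆ corrected default ⊆ adjusted
priors, in significant-voxel counts).  An alternative
("bonferroni-quantile", σ(m) = σ₀·tan(π(½ − 1/(4m)))) inflates the scale
linearly in m so the central prior mass in a fixed window shrinks like
1/m; at realistic map sizes it is even stricter than Bonferroni FWE,
which is why it is not the default.  No quantitative claim in the test
suite depends on this baseline's exact values, only on its ordering
contracts (σ(1) = σ₀, non-decreasing in m).

**Frequentist baseline.**  One-sample t maps thresholded at a
Bonferroni-corrected level α/m (α = .05, m = in-mask voxel count),
one-sided by default to match Task > Control contrasts (a two-sided flag
exists).  Bonferroni stands in for random-field-theory voxelwise FWE: on
unsmoothed data the two nearly coincide, with Bonferroni slightly more
conservative; matching a specific RFT implementation's voxel counts is a
non-goal.

## Synthetic benchmark

`simulate` generates the evaluation images: a 3-D grid (default
40×40×30 = 48,000 voxels — the benchmark design does not fix a grid size,
so it is configurable and all scoring uses proportions, not absolute
counts) in which a target proportion R of voxels are true positives with
intensity 1 (so the generating contrast is C = 1), arranged as discrete
spheres of radius 3 voxels at uniformly sampled non-overlapping centers
(rejection sampling, seeded); the final sphere is trimmed center-out —
ties in distance broken lexicographically — so the achieved count equals
round(R·48,000) exactly.  Per-subject images add i.i.d. Gaussian noise
with SD .50, untruncated.  The condition grid mirrors the benchmark:
R from .01% to 25.60% (doublings), n ∈ {8, 12, 16, 20}, 10 repetitions
per condition; one truth image per R, fresh noise per (n, repetition).
The reduced grid used by the routine checks and the acceptance script
(R ∈ {.1%, .8%, 6.4%}, n ∈ {8, 20}, 10 reps) keeps the full design's
dynamic range — rare, moderate and common activation at the smallest and
largest sample size — while finishing in about a minute on one CPU.

For adjusted-prior runs on simulated data, the a priori information is
the generating model itself (C = signal, N = noise SD, R = condition
proportion): the simulation tests the inference machinery under a
correctly specified prior elicitation, which is the intended benchmark
reading.

What the generator does *not* emulate about real fMRI: spatial
autocorrelation (no smoothing), anatomically shaped masks and brain
geometry, between-subject effect-size heterogeneity, and non-Gaussian
noise.  Passing the simulation checks therefore demonstrates correctness
of the statistics and the claimed method orderings under the stated
generative model, not performance on real scanner data; the pass-through
analysis of real NIfTI stacks exists precisely so users can run their own
data.

Randomness: one named generator (numpy PCG64); per-condition substreams
are spawned from the master seed via `SeedSequence([master, kind, i_R,
i_n, rep])`, so any single condition can be regenerated independently and
two runs with one seed are byte-identical, including CSV output.

## Scoring

Against known truth, per repetition:

* FPR = n_false_positive / n_detected — note this denominator makes it a
  **false-discovery proportion** (the name FPR is kept for continuity
  with the evaluation convention implemented here); no detections ⇒ 0.
* HR = n_true_positive / n_truth — recall; undefined (NaN, with a
  warning) when the truth is empty, and such conditions are excluded from
  grid summaries.

Between two thresholded maps without ground truth, the overlap index
I = 2|V_ovl| / (|V_org| + |V_tar|): the harmonic mean of the two overlap
fractions, algebraically the Dice coefficient, symmetric, in [0, 1];
two empty masks give 0 with a warning.

## Numerical and interface conventions

* Thresholds are inclusive: BF ≥ cutoff (default 3); p < α/m strict.
* Voxel indices are 0-based internally; affines are never resampled or
  reoriented, and stacked volumes must agree in shape and affine
  (elementwise tolerance 1e−4).
* Emitted masks are uint8 {0, 1}; scalar maps float64 with NaN
  out-of-mask.
* `solve_scale` closed form vs root-finder tolerance: 1e−10 relative;
  bisection CDF residual tolerance: 1e−12 absolute.

## Known limitations

* One global prior for all voxels; no voxel-specific or spatially varying
  elicitation.
* One-sample designs only: no covariates, paired/two-sample tests, or
  first-level modeling.
* The corrected-default rule is a documented convention, not a derivation
  from a stated loss or error-rate target.
* P must be chosen by the analyst; the package deliberately does not pick
  it.
* Inference quality on real data inherits everything the benchmark does
  not model (see above).
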