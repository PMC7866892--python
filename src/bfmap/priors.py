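"""Adjusting the scale of a Cauchy effect-size prior from a priori information.

The prior on the standardized effect size delta is Cauchy(x0 = 0, sigma).
Three quantities summarize what relevant earlier studies (typically an
image-based meta-analysis) tell us about the effect we are about to test:

* ``C`` -- the contrast, i.e. the difference between the mean activity of
  significant and non-significant voxels in the reference map (image units);
* ``N`` -- the noise strength, the standard deviation of voxel activity
  (image units);
* ``R`` -- the proportion of analyzed voxels that were significant.

Their combination ``X = (C / N) * R`` is the effect size we expect a priori
in a voxel that truly activates.  The scale sigma is then chosen so that the
prior's cumulative mass below X equals a target percentile P (e.g. 95%):
``P = F_Cauchy(X; 0, sigma)``, which has the closed form
``sigma = X / tan(pi * (P - 1/2))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize


class PriorEstimationError(ValueError):
    """Raised when C, N, R cannot be estimated from a reference map."""


@dataclass(frozen=True)
class CauchyPrior:
    """Cauchy prior on the standardized effect size.

    Parameters
    ----------
    sigma : float
        Scale of the distribution, > 0.  The conventional default in the
        Bayes-factor t-test literature is ``1/sqrt(2) = .707``.
    x0 : float
        Location. Fixed at 0 here: the hypotheses compared are
        "no effect" vs "some nonzero effect", both centered on zero.
    """

    sigma: float
    x0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be finite and > 0, got {self.sigma}")
        if self.x0 != 0.0:
            raise ValueError("only zero-centered priors are supported (x0 = 0)")


DEFAULT_PRIOR = CauchyPrior(sigma=1.0 / np.sqrt(2.0))


@dataclass(frozen=True)
class PriorInfo:
    """A priori quantities from which an adjusted prior scale is derived.

    ``X`` is derived, not stored: ``X = (C / N) * R``.
    ``P`` is the target cumulative prior mass below X, in (0.5, 1).
    """

    C: float
    N: float
    R: float
    P: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.N) or self.N <= 0:
            raise ValueError(f"noise strength N must be > 0, got {self.N}")
        if not 0.0 <= self.R <= 1.0:
            raise ValueError(f"proportion R must be in [0, 1], got {self.R}")
        if self.P is not None and not 0.5 < self.P < 1.0:
            raise ValueError(f"target mass P must be in (0.5, 1), got {self.P}")

    @property
    def X(self) -> float:
        return expected_effect(self.C, self.N, self.R)

    def with_p(self, P: float) -> "PriorInfo":
        return replace(self, P=P)


@dataclass(frozen=True)
class MetaMapSummary:
    """Voxel-count and moment summary of a reference (meta-analysis) map."""

    n_sig: int
    n_nonsig: int
    mean_sig: float
    mean_nonsig: float
    sd_all: float
    sd_sig: float = field(default=float("nan"))
    sd_nonsig: float = field(default=float("nan"))


def expected_effect(C: float, N: float, R: float) -> float:
    """Expected standardized effect ``X = (C / N) * R``.

    ``C/N`` is the standardized contrast (a Cohen's-d-like quantity) and R
    discounts it by how rare true activation is expected to be.
    """
    if not np.isfinite(N) or N <= 0:
        raise ValueError(f"noise strength N must be > 0, got {N}")
    if not 0.0 <= R <= 1.0:
        raise ValueError(f"proportion R must be in [0, 1], got {R}")
    return (C / N) * R


def cauchy_cdf(x, prior: CauchyPrior | float):
    """CDF of the Cauchy prior: ``1/2 + arctan((x - x0)/sigma) / pi``."""
    if isinstance(prior, CauchyPrior):
        x0, sigma = prior.x0, prior.sigma
    else:
        x0, sigma = 0.0, float(prior)
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return 0.5 + np.arctan((np.asarray(x, dtype=float) - x0) / sigma) / np.pi


def solve_scale(X: float, P: float, verify: bool = True) -> float:
    """Scale sigma of a zero-centered Cauchy whose CDF at ``X`` equals ``P``.

    Closed form ``sigma = X / tan(pi * (P - 1/2))``; for P in (0.5, 1) and
    X > 0 this is the unique positive solution.  When ``verify`` is true the
    closed form is cross-checked against a bracketing root-finder on the CDF
    residual and required to agree to 1e-10 relative error.
    """
    if not np.isfinite(X) or X <= 0:
        raise ValueError(
            f"expected effect X must be > 0 (got {X}); for P > .5 no positive "
            "scale exists otherwise. Re-orient the contrast so the expected "
            "effect is positive."
        )
    if not 0.5 < P < 1.0:
        raise ValueError(f"target mass P must be in (0.5, 1), got {P}")
    sigma = X / np.tan(np.pi * (P - 0.5))
    if verify:
        resid = lambda s: cauchy_cdf(X, CauchyPrior(s)) - P  # noqa: E731
        lo, hi = sigma * 0.5, sigma * 2.0
        sigma_num = optimize.brentq(resid, lo, hi, xtol=1e-300, rtol=1e-14)
        if abs(sigma_num - sigma) > 1e-10 * sigma:
            raise RuntimeError(
                f"closed-form and numeric scale disagree: {sigma} vs {sigma_num}"
            )
    return sigma


def solve_scale_bisect(X: float, P: float, cdf_tol: float = 1e-12) -> float:
    """Bracketing bisection for the adjusted scale (independent slow path).

    Searches sigma in (eps, X * 1e6) for a root of the CDF residual, to an
    absolute tolerance ``cdf_tol`` on the residual.  Kept as the numerical
    cross-check of :func:`solve_scale`'s closed form.
    """
    if not np.isfinite(X) or X <= 0:
        raise ValueError(f"expected effect X must be > 0, got {X}")
    if not 0.5 < P < 1.0:
        raise ValueError(f"target mass P must be in (0.5, 1), got {P}")
    lo, hi = X * 1e-12, X * 1e6
    flo = cauchy_cdf(X, CauchyPrior(lo)) - P
    fhi = cauchy_cdf(X, CauchyPrior(hi)) - P
    if flo * fhi > 0:
        raise RuntimeError("bisection bracket does not contain a root")
    for _ in range(20000):
        mid = 0.5 * (lo + hi)
        fmid = cauchy_cdf(X, CauchyPrior(mid)) - P
        if abs(fmid) < cdf_tol and (hi - lo) < 1e-12 * mid:
            return mid
        if flo * fmid <= 0:
            hi = mid
        else:
            lo, flo = mid, fmid
    return 0.5 * (lo + hi)


def summarize_meta_map(meta_map, sig_mask, analysis_mask=None) -> MetaMapSummary:
    """Count/moment summary of a reference map split by significance.

    ``sig_mask`` must be a subset of ``analysis_mask`` (defaults to all
    voxels).  Any nonzero mask voxel counts as in-mask.
    """
    data = np.asarray(meta_map, dtype=float)
    sig = np.asarray(sig_mask) != 0
    if analysis_mask is None:
        mask = np.ones(data.shape, dtype=bool)
    else:
        mask = np.asarray(analysis_mask) != 0
    if data.shape != sig.shape or data.shape != mask.shape:
        raise ValueError("meta map and masks must share one grid")
    if np.any(sig & ~mask):
        raise ValueError("significance mask must be a subset of the analysis mask")
    if mask.sum() < 2:
        raise PriorEstimationError("analysis mask must contain at least 2 voxels")
    nonsig = mask & ~sig
    n_sig, n_nonsig = int(sig.sum()), int(nonsig.sum())
    if n_sig == 0 or n_nonsig == 0:
        raise PriorEstimationError(
            "need at least one significant and one non-significant voxel "
            f"(got {n_sig} / {n_nonsig}); the contrast C is undefined otherwise"
        )
    vals = data[mask]
    return MetaMapSummary(
        n_sig=n_sig,
        n_nonsig=n_nonsig,
        mean_sig=float(data[sig].mean()),
        mean_nonsig=float(data[nonsig].mean()),
        sd_all=float(vals.std(ddof=1)),
        sd_sig=float(data[sig].std(ddof=1)) if n_sig > 1 else float("nan"),
        sd_nonsig=float(data[nonsig].std(ddof=1)) if n_nonsig > 1 else float("nan"),
    )


def estimate_parameters(
    meta_map,
    sig_mask,
    analysis_mask=None,
    noise_estimator: str = "all",
) -> PriorInfo:
    """Estimate (C, N, R) from a reference effect map and significance mask.

    C is the difference between the mean activity of significant and
    non-significant voxels; R the proportion of in-mask voxels that are
    significant.  N is a standard deviation of activity: over all in-mask
    voxels by default (``noise_estimator="all"``), or restricted to the
    significant (``"sig"``) or non-significant (``"nonsig"``) set.  Sample
    standard deviations (n - 1 denominator) throughout.
    """
    s = summarize_meta_map(meta_map, sig_mask, analysis_mask)
    if noise_estimator == "all":
        N = s.sd_all
    elif noise_estimator == "sig":
        N = s.sd_sig
    elif noise_estimator == "nonsig":
        N = s.sd_nonsig
    else:
        raise ValueError(f"unknown noise estimator {noise_estimator!r}")
    if not np.isfinite(N) or N <= 0:
        raise PriorEstimationError(
            f"noise strength estimate is {N}; a strictly positive activity "
            "SD is required"
        )
    C = s.mean_sig - s.mean_nonsig
    R = s.n_sig / (s.n_sig + s.n_nonsig)
    return PriorInfo(C=C, N=N, R=R)


def adjust_prior(info: PriorInfo, P: float | None = None) -> CauchyPrior:
    """Adjusted Cauchy prior from a priori information.

    Composes :func:`expected_effect` and :func:`solve_scale`; the result is
    ``Cauchy(0, sigma)`` with sigma pinning the prior's cumulative mass at
    the expected effect X to the target percentile P.
    """
    if P is None:
        P = info.P
    if P is None:
        raise ValueError("target mass P must be given (in PriorInfo or as argument)")
    return CauchyPrior(sigma=solve_scale(info.X, P))
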