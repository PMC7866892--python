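"""Synthetic evaluation images: sphere-shaped truths plus Gaussian noise.

The generator emulates the benchmark used to evaluate the analysis methods:
a 3-D grid in which a target proportion R of voxels are true positives with
intensity ``signal`` (default 1) arranged as discrete spheres, all other
voxels 0.  Per-subject images add i.i.d. Gaussian noise with SD
``noise_sd`` (default .50).  Everything is deterministic given the seed;
per-condition substreams are derived from the master seed so each condition
is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import bf_map, corrected_default_scale, threshold_bf
from .evaluate import fpr_hr
from .frequentist import fwe_threshold, t_map
from .io import VolumeStack
from .priors import CauchyPrior, PriorInfo, adjust_prior

__all__ = [
    "SimulationSpec",
    "TruthImage",
    "make_truth",
    "add_noise",
    "run_grid",
    "PAPER_R_GRID",
    "PAPER_N_GRID",
]

#: The full condition grids of the reference evaluation design.
PAPER_R_GRID = (
    0.0001, 0.0002, 0.0005, 0.0010, 0.0020, 0.0040,
    0.0080, 0.0160, 0.0320, 0.0640, 0.1280, 0.2560,
)
PAPER_N_GRID = (8, 12, 16, 20)


class SpherePackingError(RuntimeError):
    """Raised when the requested truth proportion cannot be packed as spheres."""


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic condition."""

    shape: tuple = (40, 40, 30)
    R: float = 0.016
    signal: float = 1.0
    noise_sd: float = 0.50
    n: int = 8
    n_reps: int = 10
    seed: int = 0
    radius: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.R <= 1.0:
            raise ValueError(f"R must be in [0, 1], got {self.R}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


@dataclass(frozen=True)
class TruthImage:
    """Noise-free ground truth: intensity volume and true-positive mask."""

    intensity: np.ndarray
    truth_mask: np.ndarray
    achieved_R: float = field(default=float("nan"))


def _sphere_offsets(radius: int) -> np.ndarray:
    """Voxel offsets of a discrete sphere, ordered center-out.

    Sorted by squared distance from the center, ties broken by
    lexicographic (dx, dy, dz) order, so trimming the last sphere to hit an
    exact voxel count is deterministic.
    """
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    d2 = dx**2 + dy**2 + dz**2
    keep = d2 <= r * r
    offs = np.stack([dx[keep], dy[keep], dz[keep]], axis=1)
    d2 = d2[keep]
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], d2))
    return offs[order]


def make_truth(spec: SimulationSpec) -> TruthImage:
    """Generate the sphere-packed truth image for one condition.

    Full spheres of radius ``spec.radius`` are placed at uniformly sampled,
    non-overlapping centers strictly inside the grid (rejection sampling,
    seeded); the last sphere is trimmed center-out to hit the target count
    ``round(R * grid size)`` exactly.
    """
    shape = tuple(spec.shape)
    size = int(np.prod(shape))
    target = int(round(spec.R * size))
    intensity = np.zeros(shape, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    if target == 0:
        return TruthImage(intensity=intensity, truth_mask=mask, achieved_R=0.0)
    offs = _sphere_offsets(spec.radius)
    vol = len(offs)
    r = spec.radius
    lo = np.array([r, r, r])
    hi = np.array(shape) - 1 - r
    if np.any(hi < lo):
        raise SpherePackingError(
            f"grid {shape} cannot contain a sphere of radius {r}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2**20]))
    remaining = target
    attempts = 0
    max_attempts = 200000
    while remaining > 0:
        center = rng.integers(lo, hi + 1)
        vox = center[None, :] + offs
        idx = tuple(vox.T)
        if mask[idx].any():
            attempts += 1
            if attempts > max_attempts:
                raise SpherePackingError(
                    f"could not pack {target} truth voxels as radius-{r} "
                    f"spheres into grid {shape} (R = {spec.R})"
                )
            continue
        take = min(remaining, vol)
        idx = tuple(vox[:take].T)  # center-out trim of the last sphere
        mask[idx] = True
        remaining -= take
    intensity[mask] = spec.signal
    return TruthImage(
        intensity=intensity,
        truth_mask=mask,
        achieved_R=float(mask.sum()) / size,
    )


def add_noise(truth: TruthImage, n: int, noise_sd: float, seed) -> VolumeStack:
    """Per-subject volumes: truth intensity plus i.i.d. Gaussian noise.

    Noise is independent across subjects and voxels, SD ``noise_sd``.  The
    analysis mask is the whole grid.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if noise_sd <= 0:
        raise ValueError(f"noise_sd must be > 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    shape = truth.intensity.shape
    data = truth.intensity[None, ...] + rng.normal(
        0.0, noise_sd, size=(n, *shape)
    )
    return VolumeStack(
        data=data, mask=np.ones(shape, dtype=bool), affine=np.eye(4)
    )


def _parse_method(method: str):
    """Parse a method spec string into (kind, parameter)."""
    if method == "frequentist":
        return ("frequentist", None)
    if method in ("bayes-corrected", "bayes-default-corrected"):
        return ("bayes-corrected", None)
    if method.startswith("bayes-adjusted:"):
        p = float(method.split(":", 1)[1])
        if not 0.5 < p < 1.0:
            raise ValueError(f"P must be in (0.5, 1), got {p} in {method!r}")
        return ("bayes-adjusted", p)
    raise ValueError(
        f"unknown method {method!r}; expected 'frequentist', "
        "'bayes-corrected' or 'bayes-adjusted:<P>'"
    )


def run_grid(
    R_list,
    n_list,
    n_reps: int,
    methods,
    master_seed: int = 0,
    shape=(40, 40, 30),
    signal: float = 1.0,
    noise_sd: float = 0.50,
    bf_cutoff: float = 3.0,
    alpha: float = 0.05,
    radius: int = 3,
) -> pd.DataFrame:
    """Run the simulation study over a condition grid.

    One truth image is generated per proportion R (as in the reference
    design: one simulated image per proportion); noise sets vary with the
    sample size n and repetition.  For the adjusted-prior methods the a
    priori information is the generating truth itself: C = ``signal``,
    N = ``noise_sd``, R = the condition's target proportion.

    Returns a tidy table with one row per (R, n, rep, method) holding the
    confusion counts, FPR and HR, and the prior scale used (NaN for the
    frequentist baseline).
    """
    parsed = [(m, *_parse_method(m)) for m in methods]
    n_vox = int(np.prod(shape))
    rows = []
    for i_r, R in enumerate(R_list):
        truth = make_truth(
            SimulationSpec(
                shape=tuple(shape), R=R, signal=signal, noise_sd=noise_sd,
                n=max(n_list), seed=_cond_seed(master_seed, i_r), radius=radius,
            )
        )
        # a priori adjusted scales for this proportion condition
        sigmas = {}
        for name, kind, p in parsed:
            if kind == "bayes-adjusted":
                info = PriorInfo(C=signal, N=noise_sd, R=R, P=p)
                sigmas[name] = adjust_prior(info).sigma
            elif kind == "bayes-corrected":
                sigmas[name] = corrected_default_scale(n_vox)
        for i_n, n in enumerate(n_list):
            for rep in range(n_reps):
                stack = add_noise(
                    truth, n, noise_sd,
                    np.random.SeedSequence(
                        [int(master_seed), 1, i_r, i_n, rep]
                    ),
                )
                tm = None
                bf_cache = {}
                for name, kind, p in parsed:
                    if kind == "frequentist":
                        if tm is None:
                            tm = t_map(stack)
                        det = fwe_threshold(tm, alpha=alpha)
                        sigma = float("nan")
                    else:
                        sigma = sigmas[name]
                        if sigma not in bf_cache:
                            bf_cache[sigma] = bf_map(stack, CauchyPrior(sigma))
                        det = threshold_bf(bf_cache[sigma], cutoff=bf_cutoff)
                    res = fpr_hr(det, truth.truth_mask)
                    rows.append(
                        {
                            "R": R,
                            "n": n,
                            "rep": rep,
                            "method": name,
                            "sigma": sigma,
                            "fpr": res.fpr,
                            "hr": res.hr,
                            "n_detected": res.n_noise_positive,
                            "n_true_positive": res.n_true_positive,
                            "n_false_positive": res.n_false_positive,
                            "n_truth": res.n_original_positive,
                        }
                    )
    return pd.DataFrame(rows)


def _cond_seed(master_seed: int, i_r: int) -> int:
    """Derived truth-image seed for proportion condition ``i_r``."""
    ss = np.random.SeedSequence([int(master_seed), 0, i_r])
    return int(ss.generate_state(1, dtype=np.uint32)[0])
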