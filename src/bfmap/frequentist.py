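"""Classical one-sample t-test with voxelwise family-wise-error control.

The comparison baseline: per-voxel one-sample t statistics thresholded at a
Bonferroni-corrected level.  Bonferroni is a deliberately simple stand-in
for random-field-theory FWE; on unsmoothed data (as in the simulations
here) the two are close, with Bonferroni slightly more conservative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bayes import BinaryMask

__all__ = ["TMap", "t_map", "fwe_threshold"]


@dataclass(frozen=True)
class TMap:
    """Voxelwise t statistics with their degrees of freedom."""

    t: np.ndarray  # NaN outside mask / at excluded voxels
    df: int
    mask: np.ndarray
    n_excluded: int = 0


def t_map(stack) -> TMap:
    """Per-voxel one-sample t statistic ``mean / (sd / sqrt(n))``, df = n-1.

    Zero-variance voxels are excluded (NaN) with a warning.
    """
    data = stack.data
    mask = stack.mask
    n = stack.n
    flat = data.reshape(n, -1)[:, mask.ravel()]
    sd = flat.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} in-mask voxel(s) have zero variance across "
            "subjects and were excluded from the t map",
            stacklevel=2,
        )
    tv = np.full(flat.shape[1], np.nan)
    ok = ~bad
    tv[ok] = flat[:, ok].mean(axis=0) / (sd[ok] / np.sqrt(n))
    out = np.full(mask.shape, np.nan)
    out[mask] = tv
    return TMap(t=out, df=n - 1, mask=mask, n_excluded=int(bad.sum()))


def fwe_threshold(
    tmap: TMap,
    alpha: float = 0.05,
    n_voxels: int | None = None,
    sides: str = "one",
) -> BinaryMask:
    """Bonferroni voxelwise FWE threshold of a t map.

    A voxel is significant iff its p-value is below ``alpha / n_voxels``.
    ``n_voxels`` defaults to the number of in-mask voxels.  One-sided
    (activation > 0) by default, matching Task > Control contrasts; pass
    ``sides="two"`` for two-sided p-values.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if n_voxels is None:
        n_voxels = int(tmap.mask.sum())
    if n_voxels < 1:
        raise ValueError(f"n_voxels must be >= 1, got {n_voxels}")
    t = tmap.t
    with np.errstate(invalid="ignore"):
        if sides == "one":
            p = stats.t.sf(t, tmap.df)
        elif sides == "two":
            p = 2.0 * stats.t.sf(np.abs(t), tmap.df)
        else:
            raise ValueError(f"sides must be 'one' or 'two', got {sides!r}")
        sig = (p < alpha / n_voxels) & tmap.mask & np.isfinite(t)
    return BinaryMask(
        mask=sig.astype(np.uint8),
        rule=f"p < {alpha:g}/{n_voxels} (Bonferroni voxelwise FWE, {sides}-sided)",
    )
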