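"""Detection-performance metrics for thresholded voxel maps.

Two kinds of comparison are used:

* against a known ground truth (simulations): the false-positive rate and
  the hit rate.  Note the FPR here divides false detections by *all*
  detections -- it is a false-discovery proportion, kept under the name
  ``fpr`` for continuity with the evaluation convention it implements;
* between two thresholded maps with no ground truth (real data vs a
  meta-analysis): a Dice-type overlap index in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["EvalResult", "OverlapResult", "fpr_hr", "overlap_index"]


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and rates of a detection mask against a truth mask."""

    n_false_positive: int
    n_noise_positive: int  # all detections
    n_true_positive: int
    n_original_positive: int  # truth size
    fpr: float  # false detections / all detections (false-discovery proportion)
    hr: float  # true detections / truth size (recall); NaN if truth empty


@dataclass(frozen=True)
class OverlapResult:
    """Dice-type overlap between two binary maps."""

    index: float
    v_ovl: int
    v_org: int
    v_tar: int


def _as_bool(mask) -> np.ndarray:
    m = getattr(mask, "mask", mask)
    return np.asarray(m) != 0


def fpr_hr(detected, truth) -> EvalResult:
    """False-positive rate and hit rate of ``detected`` against ``truth``.

    FPR = n_false_positive / n_noise_positive where n_noise_positive is the
    total number of detected voxels; HR = n_true_positive /
    n_original_positive.  With no detections the FPR is 0 (nothing was
    falsely discovered); with an empty truth the HR is undefined (NaN).
    """
    det = _as_bool(detected)
    tru = _as_bool(truth)
    if det.shape != tru.shape:
        raise ValueError(
            f"detected and truth masks differ in shape: {det.shape} vs {tru.shape}"
        )
    n_det = int(det.sum())
    n_tp = int((det & tru).sum())
    n_fp = n_det - n_tp
    n_org = int(tru.sum())
    fpr = n_fp / n_det if n_det > 0 else 0.0
    if n_org > 0:
        hr = n_tp / n_org
    else:
        warnings.warn("truth mask is empty; hit rate is undefined", stacklevel=2)
        hr = float("nan")
    return EvalResult(
        n_false_positive=n_fp,
        n_noise_positive=n_det,
        n_true_positive=n_tp,
        n_original_positive=n_org,
        fpr=fpr,
        hr=hr,
    )


def overlap_index(original, target) -> OverlapResult:
    """Overlap index I = 2|V_ovl| / (|V_org| + |V_tar|).

    The harmonic mean of the two overlap fractions a = |V_ovl|/|V_org| and
    b = |V_ovl|/|V_tar| (i.e. 2ab/(a+b)), which simplifies to the Dice
    coefficient above.  Symmetric in its arguments; 0 = no overlap,
    1 = identical nonempty masks.  Two empty masks give 0 with a warning.
    """
    org = _as_bool(original)
    tar = _as_bool(target)
    if org.shape != tar.shape:
        raise ValueError(
            f"original and target masks differ in shape: {org.shape} vs {tar.shape}"
        )
    v_org = int(org.sum())
    v_tar = int(tar.sum())
    v_ovl = int((org & tar).sum())
    if v_org + v_tar == 0:
        warnings.warn(
            "both masks are empty; overlap index reported as 0", stacklevel=2
        )
        idx = 0.0
    else:
        idx = 2.0 * v_ovl / (v_org + v_tar)
    return OverlapResult(index=idx, v_ovl=v_ovl, v_org=v_org, v_tar=v_tar)
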