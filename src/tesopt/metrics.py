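"""Intensity and focality metrics for montage solutions.

Both focality definitions are ratios of the mean directional intensity at the
ROI to a non-ROI exposure measure, hence unitless and invariant to pattern
scaling:

* integral focality — exposure as the root-mean field energy over the
  non-ROI (natural for the energy-integral constraint);
* elementwise focality — exposure as the peak field magnitude over the
  non-ROI (natural for the per-element constraint).
"""

from __future__ import annotations

import warnings

import numpy as np

from .fem import TransferMatrix
from .problem import TargetSpec, VolumeWeights

__all__ = [
    "mean_roi_intensity",
    "integral_focality",
    "elementwise_focality",
]


def mean_roi_intensity(
    i: np.ndarray, T: TransferMatrix, weights: VolumeWeights, target: TargetSpec
) -> float:
    """Mean directional field over the ROI, V/m: (d' Gamma T i) / Vol_ROI."""
    num = float((weights.gamma * target.d) @ (T.values @ i))
    return num / target.roi_volume


def integral_focality(
    i: np.ndarray, T: TransferMatrix, weights: VolumeWeights, target: TargetSpec
) -> float:
    """Mean ROI intensity over the RMS non-ROI field (volume-weighted)."""
    num = mean_roi_intensity(i, T, weights, target)
    f = T.values @ i
    energy = float(f @ (weights.gamma_nonroi * f))
    if energy <= 0:
        warnings.warn("zero non-ROI field energy; integral focality is infinite")
        return float("inf") if num > 0 else float("nan")
    return num / float(np.sqrt(energy / weights.nonroi_volume))


def elementwise_focality(
    i: np.ndarray, T: TransferMatrix, weights: VolumeWeights, target: TargetSpec
) -> float:
    """Mean ROI intensity over the peak non-ROI field magnitude."""
    num = mean_roi_intensity(i, T, weights, target)
    F = T.field_of(i)
    norms = np.linalg.norm(F, axis=1)[weights.nonroi_mask_elements]
    peak = float(norms.max()) if norms.size else 0.0
    if peak <= 0:
        warnings.warn("zero non-ROI field; elementwise focality is infinite")
        return float("inf") if num > 0 else float("nan")
    return num / peak
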