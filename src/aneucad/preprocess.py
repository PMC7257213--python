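"""Intensity preprocessing for TOF-MRA volumes.

The pipeline's first stage conditions raw angiography intensities before
any geometry is touched: a multiplicative bias (coil shading) field is
estimated and divided out, histograms are aligned across scans, and the
vessel band is stretched with a sigmoid remap

    f(x) = (Max - Min) * 1 / (1 + exp(-(x - beta) / alpha)) + Min

with ``alpha = 400`` (width) and ``beta = 600`` (centre) by default.
``Max``/``Min`` default to the input volume's own extrema so the sigmoid
is a contrast remap within the native dynamic range — this keeps later
relative thresholds (e.g. 30 % of the maximum) meaningful.

All operations preserve grid metadata exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .volume_io import Volume

__all__ = [
    "SigmoidParams",
    "correct_bias_field",
    "histogram_normalize",
    "sigmoid_enhance",
    "histogram_equalize",
]


@dataclass
class SigmoidParams:
    """Parameters of the sigmoid vessel-enhancement remap.

    ``out_min`` / ``out_max`` of ``None`` mean "use the input volume's
    min / max", preserving the dynamic range.
    """

    alpha: float = 400.0
    beta: float = 600.0
    out_min: float | None = None
    out_max: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if (
            self.out_min is not None
            and self.out_max is not None
            and not self.out_max > self.out_min
        ):
            raise ValueError("out_max must exceed out_min")


def correct_bias_field(
    v: Volume,
    fitting_levels: int = 3,
    iterations_per_level: int = 50,
    shrink_factor: int = 2,
) -> Volume:
    """Remove a smooth multiplicative bias field (N4 algorithm).

    The field is estimated iteratively in the log domain on a shrunk copy
    of the image and divided out at full resolution; the output is then
    rescaled so the mean intensity is preserved.  Requires non-negative
    intensities; raises on an all-zero volume.
    """
    data = np.asarray(v.data, dtype=np.float64)
    if data.min() < 0:
        raise ValueError("bias correction requires non-negative intensities")
    if not np.any(data > 0):
        raise ValueError("all-zero volume: nothing to correct")
    fg = data[data > 0]
    if fg.std() / fg.mean() < 1e-3:
        # (near-)constant image: the histogram-sharpening step of the field
        # estimator is degenerate and there is no bias to remove
        return v.with_data(data.astype(v.data.dtype, copy=False))

    img = sitk.GetImageFromArray(data.astype(np.float32))
    img.SetSpacing(tuple(reversed(v.spacing)))
    mask = sitk.GetImageFromArray((data > 0).astype(np.uint8))
    mask.CopyInformation(img)

    shrink = max(1, int(shrink_factor))
    small = sitk.Shrink(img, [shrink] * 3)
    small_mask = sitk.Shrink(mask, [shrink] * 3)

    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.SetMaximumNumberOfIterations([int(iterations_per_level)] * int(fitting_levels))
    corrector.Execute(small, small_mask)

    log_field = corrector.GetLogBiasFieldAsImage(img)
    field = np.exp(sitk.GetArrayFromImage(log_field)).astype(np.float64)
    corrected = data / np.maximum(field, 1e-12)

    # N4 fixes shape, not scale: restore the global mean.
    in_mean = data.mean()
    out_mean = corrected.mean()
    if out_mean > 0:
        corrected *= in_mean / out_mean
    return v.with_data(corrected.astype(v.data.dtype, copy=False))


def _deciles(values: np.ndarray) -> np.ndarray:
    return np.percentile(values, np.arange(0, 101, 10))


def histogram_normalize(v: Volume, reference: Volume) -> Volume:
    """Align ``v``'s foreground intensity deciles to a reference scan.

    A monotone piecewise-linear map sends the deciles of ``v``'s
    foreground (voxels above the volume minimum) onto the reference's.
    Raises on a degenerate (single-valued) histogram.
    """
    src = np.asarray(v.data, dtype=np.float64)
    ref = np.asarray(reference.data, dtype=np.float64)
    src_fg = src[src > src.min()]
    ref_fg = ref[ref > ref.min()]
    if src_fg.size == 0 or np.ptp(src_fg) == 0:
        raise ValueError("degenerate histogram: volume has no intensity spread")
    if ref_fg.size == 0 or np.ptp(ref_fg) == 0:
        raise ValueError("degenerate histogram: reference has no intensity spread")
    src_q = _deciles(src_fg)
    ref_q = _deciles(ref_fg)
    # np.interp requires strictly usable breakpoints; collapse duplicates.
    keep = np.concatenate([[True], np.diff(src_q) > 0])
    mapped = np.interp(src, src_q[keep], ref_q[keep])
    return v.with_data(mapped.astype(v.data.dtype, copy=False))


def sigmoid_enhance(v: Volume, p: SigmoidParams | None = None) -> Volume:
    """Voxelwise sigmoid contrast remap emphasising the vessel band."""
    p = p or SigmoidParams()
    data = np.asarray(v.data, dtype=np.float64)
    lo = float(data.min()) if p.out_min is None else float(p.out_min)
    hi = float(data.max()) if p.out_max is None else float(p.out_max)
    if not hi > lo:
        raise ValueError("sigmoid output range is empty (constant volume?)")
    with np.errstate(over="ignore"):  # deep-tail exp overflow saturates to lo
        out = (hi - lo) / (1.0 + np.exp(-(data - p.beta) / p.alpha)) + lo
    return v.with_data(out)


def histogram_equalize(v: Volume) -> Volume:
    """Classic CDF-based histogram equalization over the full volume.

    The output spans the input's intensity range and preserves the rank
    order of voxel intensities.  Raises on a constant volume.
    """
    data = np.asarray(v.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise ValueError("constant volume cannot be equalized")
    values, inverse, counts = np.unique(data, return_inverse=True, return_counts=True)
    cdf = np.cumsum(counts).astype(np.float64) / data.size
    out = (lo + (hi - lo) * cdf[inverse]).reshape(data.shape)
    return v.with_data(out)
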