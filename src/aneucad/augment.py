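"""Training-set preparation: 8-fold augmentation, fixed-size blocks,
sphere-dilated annotations.

Each (image, labels) pair is expanded into the full factorial of three
filters — transverse flip, discrete Gaussian smoothing (variance 4.0,
max kernel width 32), and histogram equalization — applied in that
order, including the identity variant: 2^3 = 8 variants per pair (so 76
pairs become 608, 20 become 160, 96 become 768).  Intensity filters are
never applied to label volumes; only the geometric flip is.

For the detector, volumes are cropped to content and resampled to fixed
cubic blocks (128^3 at full scale), and every annotated aneurysm
component is replaced by a filled sphere of a shared radius
``max(4, ceil(0.03 * axis_length))`` at the component centroid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume_io import LabelVolume, Volume, crop_like, crop_to_content, resample_to_shape
from . import preprocess

__all__ = [
    "AugmentedSet",
    "SphereAnnotation",
    "flip_transverse",
    "discrete_gaussian",
    "augment_variants",
    "annotation_to_sphere",
    "sphere_radius_for_axis",
    "prepare_block",
]

#: The three augmentation filters, in application order.
FILTERS = ("flip", "gaussian", "histeq")


@dataclass
class AugmentedSet:
    """The 8 filter variants of one or more (Volume, LabelVolume) pairs."""

    items: list[tuple[Volume, LabelVolume]]
    provenance: list[str]  # e.g. "identity", "flip+gaussian"

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class SphereAnnotation:
    """Sphere-marker form of the aneurysm annotations of one volume."""

    centers: list[tuple[int, int, int]]
    radius: int


def flip_transverse(v):
    """Reverse the slice (superior-inferior) axis; metadata unchanged."""
    if isinstance(v, LabelVolume):
        return LabelVolume(v.labels[::-1].copy(), v.spacing, v.origin, legend=dict(v.legend))
    return Volume(v.data[::-1].copy(), v.spacing, v.origin)


def discrete_gaussian(v: Volume, variance: float = 4.0, max_kernel_width: int = 32) -> Volume:
    """Discrete Gaussian smoothing (Lindeberg kernel, separable).

    ``variance`` is in voxel^2; the sampled kernel is normalized and
    truncated to at most ``max_kernel_width`` taps per axis, so a
    constant volume passes through unchanged.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0:
        return v.with_data(v.data.copy())
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.astype(np.float64)))
    # filter in voxel units: unit spacing regardless of the physical grid
    flt = sitk.DiscreteGaussianImageFilter()
    flt.SetVariance(float(variance))
    flt.SetMaximumKernelWidth(int(max_kernel_width))
    flt.SetUseImageSpacing(False)
    out = sitk.GetArrayFromImage(flt.Execute(img))
    return v.with_data(out.astype(v.data.dtype, copy=False))


def _apply_variant(
    pair: tuple[Volume, LabelVolume],
    do_flip: bool,
    do_gauss: bool,
    do_histeq: bool,
    variance: float = 4.0,
    max_kernel_width: int = 32,
) -> tuple[Volume, LabelVolume]:
    img, lab = pair
    if do_flip:
        img = flip_transverse(img)
        lab = flip_transverse(lab)
    if do_gauss:
        img = discrete_gaussian(img, variance, max_kernel_width)
    if do_histeq:
        img = preprocess.histogram_equalize(img)
    return img, lab


def augment_variants(
    pair: tuple[Volume, LabelVolume],
    variance: float = 4.0,
    max_kernel_width: int = 32,
) -> AugmentedSet:
    """All 2^3 = 8 apply/skip combinations of flip, Gaussian, equalize.

    Filters run in that fixed order; labels undergo only the flip.  The
    identity variant (no filter) is included and tagged ``"identity"``.
    """
    items, provenance = [], []
    for do_flip, do_gauss, do_histeq in itertools.product((False, True), repeat=3):
        items.append(
            _apply_variant(pair, do_flip, do_gauss, do_histeq, variance, max_kernel_width)
        )
        applied = [
            name
            for name, on in zip(FILTERS, (do_flip, do_gauss, do_histeq))
            if on
        ]
        provenance.append("+".join(applied) if applied else "identity")
    return AugmentedSet(items=items, provenance=provenance)


def augment_dataset(pairs, **kwargs) -> AugmentedSet:
    """Concatenated :func:`augment_variants` over a list of pairs."""
    items, provenance = [], []
    for i, pair in enumerate(pairs):
        s = augment_variants(pair, **kwargs)
        items.extend(s.items)
        provenance.extend(f"{i}:{p}" for p in s.provenance)
    return AugmentedSet(items=items, provenance=provenance)


def sphere_radius_for_axis(axis_length: int) -> int:
    """Shared annotation-sphere radius: above 3 voxels under a 128 axis.

    ``r = max(4, ceil(0.03 * axis_length))`` reconciles "above 3 voxels"
    with "above 3 % of the axis length" at the canonical block size.
    """
    return max(4, math.ceil(0.03 * axis_length))


def annotation_to_sphere(
    lv: LabelVolume,
    axis_length: int | None = None,
    radius: int | None = None,
    aneurysm_label: int = 2,
    vessel_label: int = 1,
) -> LabelVolume:
    """Replace each aneurysm component by a centred fixed-radius sphere.

    Component centroids are rounded to the nearest voxel; all spheres
    share one radius (from ``radius`` or the axis-length rule) and are
    clipped at the volume border.  Original aneurysm voxels outside their
    sphere revert to the vessel label.
    """
    if radius is None:
        if axis_length is None:
            axis_length = max(lv.shape)
        radius = sphere_radius_for_axis(axis_length)
    ane = lv.labels == aneurysm_label
    if not ane.any():
        raise ValueError("no aneurysm label present")
    labeled, n = ndimage.label(ane, structure=np.ones((3, 3, 3), dtype=bool))
    out = lv.labels.copy()
    out[ane] = vessel_label
    centers = []
    zz, yy, xx = np.indices(lv.shape, sparse=True)
    for lab in range(1, n + 1):
        centroid = np.argwhere(labeled == lab).mean(axis=0)
        c = tuple(int(round(x)) for x in centroid)
        centers.append(c)
        ball = (
            (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        ) <= radius * radius
        out[ball] = aneurysm_label
    return LabelVolume(out, lv.spacing, lv.origin, legend=dict(lv.legend))


def prepare_block(
    pair: tuple[Volume, LabelVolume],
    size: int = 128,
    background_threshold: float = 0.0,
) -> tuple[Volume, LabelVolume]:
    """Crop to content and resample to an exact ``size^3`` block.

    The crop box comes from the image (voxels above
    ``background_threshold``) and is applied identically to the labels;
    resampling is linear for the image, nearest for labels.
    """
    if size < 8:
        raise ValueError("block size must be >= 8")
    img, lab = pair
    if img.shape != lab.shape:
        raise ValueError("image and labels are on different grids")
    cropped = crop_to_content(img, background_threshold)
    lab_cropped = crop_like(lab, cropped, img)
    img_block = resample_to_shape(cropped, (size, size, size), mode="linear")
    lab_vol = resample_to_shape(
        Volume(lab_cropped.labels.astype(np.int16), lab.spacing, cropped.origin),
        (size, size, size),
        mode="nearest",
    )
    lab_block = LabelVolume(
        lab_vol.data.astype(np.int16), lab_vol.spacing, lab_vol.origin, legend=dict(lab.legend)
    )
    return img_block, lab_block
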