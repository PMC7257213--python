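"""Step two post-processing and the end-to-end inference pipeline.

The network's per-voxel aneurysm likelihood is binarized at 0.5 (strict
``>``), its 26-connected components become sphere markers — one
detection per component, centred at the component centroid, with the
same radius used to dilate the training annotations — and the markers
are mapped back to original-resolution world coordinates for review.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from . import preprocess, segment, unet3d
from .augment import annotation_to_sphere, sphere_radius_for_axis
from .config import PipelineConfig
from .preprocess import SigmoidParams
from .segment import VOI
from .volume_io import (
    FormatError,
    LabelVolume,
    Volume,
    crop_to_content,
    read_dicom_series,
    read_nifti,
    resample_onto,
    resample_to_shape,
)

__all__ = [
    "LikelihoodVolume",
    "Detection",
    "PipelineError",
    "PipelineResult",
    "binarize_likelihood",
    "components_to_detections",
    "run_pipeline",
    "threshold_sweep",
    "detections_to_json",
    "render_detection_mask",
]

_CONN26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class LikelihoodVolume:
    """Per-voxel aneurysm probability on a block grid; zero outside VOI."""

    probabilities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float32)
        if self.probabilities.min() < 0 or self.probabilities.max() > 1:
            raise ValueError("likelihoods must lie in [0, 1]")

    @classmethod
    def from_volume(cls, v: Volume) -> "LikelihoodVolume":
        return cls(v.data, v.spacing, v.origin)


@dataclass
class Detection:
    """One sphere marker produced from a predicted component."""

    center_index: tuple[int, int, int]  # voxel index on the detection grid
    center_mm: tuple[float, float, float]  # world coordinates
    radius_vox: float  # on the detection grid
    radius_mm: float
    score: float  # max likelihood in the component
    component_voxels: int

    def to_dict(self) -> dict:
        return asdict(self)


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    detections: list[Detection]
    mesh: "object"
    voi: VOI
    vessel_mask: np.ndarray
    likelihood: LikelihoodVolume
    block: Volume
    coverage: float | None = None


def binarize_likelihood(l: LikelihoodVolume, threshold: float = 0.5) -> np.ndarray:
    """Strict binarization: a voxel is aneurysm iff likelihood > threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return l.probabilities > threshold


def components_to_detections(
    mask: np.ndarray,
    radius: float,
    min_component_size: int = 5,
    likelihood: LikelihoodVolume | None = None,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> list[Detection]:
    """One sphere marker per sufficiently large 26-connected component.

    The marker sits at the component centroid (rounded to the nearest
    voxel); its score is the component's maximum likelihood (1.0 when no
    likelihood map is supplied).  Results are sorted by score descending,
    ties by centre index.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    mask = np.asarray(mask).astype(bool)
    if likelihood is not None:
        spacing = likelihood.spacing
        origin = likelihood.origin
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if not mask.any():
        return []
    labeled, n = ndimage.label(mask, structure=_CONN26)
    detections = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        size = int(comp.sum())
        if size < min_component_size:
            continue
        centroid = np.argwhere(comp).mean(axis=0)
        idx = tuple(int(round(c)) for c in centroid)
        score = float(likelihood.probabilities[comp].max()) if likelihood is not None else 1.0
        mm = tuple(origin + np.asarray(idx) * spacing)
        detections.append(
            Detection(
                center_index=idx,
                center_mm=tuple(float(x) for x in mm),
                radius_vox=float(radius),
                radius_mm=float(radius * spacing.mean()),
                score=score,
                component_voxels=size,
            )
        )
    detections.sort(key=lambda d: (-d.score, d.center_index))
    return detections


def threshold_sweep(
    l: LikelihoodVolume,
    thresholds,
    radius: float,
    min_component_size: int = 5,
) -> dict[float, list[Detection]]:
    """Detections per binarization threshold (counts are non-increasing)."""
    out = {}
    for t in thresholds:
        mask = binarize_likelihood(l, t)
        out[float(t)] = components_to_detections(
            mask, radius, min_component_size, likelihood=l
        )
    return out


# --- end-to-end inference ---------------------------------------------------


def _load_input(source) -> Volume:
    if isinstance(source, Volume):
        return source
    source = str(source)
    if os.path.isdir(source):
        return read_dicom_series(source)
    return read_nifti(source)


def preprocess_volume(v: Volume, config: PipelineConfig,
                      reference: Volume | None = None) -> Volume:
    """Bias correction, optional histogram normalization, sigmoid remap."""
    if config.bias_correction:
        v = preprocess.correct_bias_field(v)
    if config.histogram_normalize and reference is not None:
        v = preprocess.histogram_normalize(v, reference)
    return preprocess.sigmoid_enhance(
        v, SigmoidParams(alpha=config.sigmoid_alpha, beta=config.sigmoid_beta)
    )


def segment_stage(v: Volume, config: PipelineConfig):
    """Step one on a preprocessed volume: strip, segment, mesh, VOI."""
    stripped, _ = segment.strip_skull(
        v,
        lower_fraction=config.skull_lower_fraction,
        closing_radius=config.skull_closing_radius,
    )
    vessel_mask, model = segment.segment_vessels(
        stripped, background_value=config.background_value, top_k=config.seed_top_k
    )
    mesh = segment.extract_mesh(vessel_mask, v.spacing, v.origin)
    voi = segment.dilate_voi(vessel_mask, config.voi_radius, v.spacing, v.origin)
    return stripped, vessel_mask, model, mesh, voi


def block_for_network(stripped: Volume, voi: VOI, config: PipelineConfig):
    """Crop to content and resample image + VOI to the network block."""
    s = config.block_size
    masked = stripped.with_data(np.where(voi.mask, stripped.data, 0.0))
    cropped = crop_to_content(masked, 0.0)
    block = resample_to_shape(cropped, (s, s, s), mode="linear")
    lo = np.rint(
        (np.asarray(cropped.origin) - np.asarray(stripped.origin))
        / np.asarray(stripped.spacing)
    ).astype(int)
    hi = lo + np.asarray(cropped.shape)
    voi_crop = Volume(
        voi.mask[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]].astype(np.uint8),
        stripped.spacing,
        cropped.origin,
    )
    voi_block = resample_to_shape(voi_crop, (s, s, s), mode="nearest")
    return block, VOI(
        voi_block.data.astype(bool), voi.dilation_radius, voi_block.spacing, voi_block.origin
    )


def make_training_block(
    volume: Volume,
    labels: LabelVolume,
    config: PipelineConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One (network input, target mask) pair from an annotated volume.

    Runs preprocessing and step one, resamples image + VOI + labels onto
    the network block grid, dilates the aneurysm annotations to spheres
    of the block-space radius, and standardizes the input.  Returns
    ``(x, foreground)`` ready for :func:`aneucad.unet3d.train`.
    """
    config = config or PipelineConfig()
    pre = preprocess_volume(volume, config)
    stripped, _, _, _, voi = segment_stage(pre, config)
    block, voi_block = block_for_network(stripped, voi, config)
    lab_on_block = resample_onto(
        Volume(labels.labels.astype(np.int16), labels.spacing, labels.origin),
        block,
        mode="nearest",
    )
    lab_block = LabelVolume(
        lab_on_block.data.astype(np.int16), block.spacing, block.origin,
        legend=dict(labels.legend),
    )
    if (lab_block.labels == 2).any():
        lab_block = annotation_to_sphere(lab_block, axis_length=config.block_size)
    fg = lab_block.labels == 2
    x = unet3d.make_input(block.data, voi_block.mask)
    return x, fg


def run_pipeline(
    source,
    model: unet3d.ModelState,
    config: PipelineConfig | None = None,
    aneurysm_mask: np.ndarray | None = None,
) -> PipelineResult:
    """Full detection run: read -> preprocess -> step one -> step two.

    ``source`` is a DICOM directory, a NIfTI path, or a :class:`Volume`.
    When a ground-truth ``aneurysm_mask`` (original grid) is given the
    VOI coverage fraction is recorded on the result.  Detections carry
    world-mm coordinates valid on the original grid.
    """
    config = config or PipelineConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ValueError, FormatError, RuntimeError) as exc:
            raise PipelineError(name, exc) from exc

    v = stage("read", _load_input, source)
    pre = stage("preprocess", preprocess_volume, v, config)
    stripped, vessel_mask, _model_fit, mesh, voi = stage("segment", segment_stage, pre, config)
    coverage = None
    if aneurysm_mask is not None:
        coverage = segment.coverage_fraction(voi, aneurysm_mask)
    block, voi_block = stage("block", block_for_network, stripped, voi, config)
    prob = stage("predict", unet3d.predict, model, block, voi_block)
    likelihood = LikelihoodVolume.from_volume(prob)
    mask = binarize_likelihood(likelihood, config.likelihood_threshold)
    radius = sphere_radius_for_axis(config.block_size)
    detections = components_to_detections(
        mask, radius, config.min_component_size, likelihood=likelihood
    )
    return PipelineResult(
        detections=detections,
        mesh=mesh,
        voi=voi,
        vessel_mask=vessel_mask,
        likelihood=likelihood,
        block=block,
        coverage=coverage,
    )


def detections_to_json(detections: list[Detection], path, case_id: str = "") -> None:
    payload = {"case_id": case_id, "detections": [d.to_dict() for d in detections]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def render_detection_mask(
    detections: list[Detection], shape, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Sphere markers rendered as a binary overlay on an arbitrary grid."""
    out = np.zeros(shape, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    zz, yy, xx = np.indices(shape, sparse=True)
    for det in detections:
        c = (np.asarray(det.center_mm) - origin) / spacing
        r_vox = det.radius_mm / spacing.mean()
        ball = (
            (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        ) <= r_vox * r_vox
        out |= ball
    return out
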