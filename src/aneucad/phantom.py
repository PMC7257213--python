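"""Seeded synthetic TOF-MRA-like phantoms with exhaustive ground truth.

A phantom emulates the intensity statistics the pipeline assumes rather
than anatomy: a dark, mildly noisy background; a bright spherical
skull/scalp shell hugging the volume periphery (the brightest structure,
so the bounding-box rays and the 30 %-of-max growing band find and
remove it); an interior arterial tree built from smoothed 3D random
walks, its voxel intensities i.i.d. Gaussian ``N(mu_v, sigma_v)``; and
aneurysms as spheres overlapping a vessel wall, sharing the vessel
intensity law.  A dark moat separates shell and tree, so skull stripping
provably cannot take vessels with it, and every aneurysm lies within
10 voxels of a vessel voxel, making full VOI coverage achievable.

An optional smooth multiplicative bias field exercises the N4 stage.
Everything is deterministic under ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .evaluate import Aneurysm, AnnotationRecord, LOCATIONS, SIZE_BINS
from .volume_io import LabelVolume, Volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort"]


@dataclass
class PhantomSpec:
    """Geometry, intensity and randomness of one synthetic phantom."""

    size: int = 64
    spacing: float = 1.0  # mm, isotropic
    background_mean: float = 50.0
    background_sd: float = 10.0
    shell_thickness: float = 2.0
    shell_intensity: float = 1200.0
    shell_margin: float = 2.0  # gap between shell and volume border
    moat: float = 4.0  # guaranteed dark gap between shell and tree
    n_branches: int = 3
    branch_length: int = 60
    vessel_radius: tuple[float, float] = (2.0, 3.0)
    vessel_mu: float = 300.0
    vessel_sigma: float = 20.0
    n_aneurysms: int = 1
    aneurysm_radius: tuple[float, float] = (3.0, 6.0)
    bias_amplitude: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("phantom size must be >= 32")
        if self.vessel_radius[0] < 1 or self.aneurysm_radius[0] < 2:
            raise ValueError("vessel radii >= 1 and aneurysm radii >= 2 required")
        if self.vessel_sigma <= 0:
            raise ValueError("vessel_sigma must be > 0")


def _ball_indices(center: np.ndarray, radius: float, size: int) -> tuple:
    """In-bounds voxel indices of the discrete ball around ``center``."""
    c = np.asarray(center, dtype=float)
    lo = np.maximum(np.floor(c - radius).astype(int), 0)
    hi = np.minimum(np.ceil(c + radius).astype(int) + 1, size)
    zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    inside = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius**2
    return zz[inside], yy[inside], xx[inside]


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _centerlines(spec: PhantomSpec, rng: np.random.Generator, limit: float,
                 center: np.ndarray) -> list[np.ndarray]:
    """Smoothed 3D random-walk centerlines confined to a ball."""
    branches: list[np.ndarray] = []
    for b in range(spec.n_branches):
        if b == 0 or not branches:
            pos = center + rng.normal(scale=3.0, size=3)
        else:
            src = branches[0]
            pos = src[rng.integers(len(src))].astype(float).copy()
        direction = _random_unit(rng)
        pts = [pos.copy()]
        for _ in range(spec.branch_length):
            direction = direction + rng.normal(scale=0.25, size=3)
            direction /= np.linalg.norm(direction)
            nxt = pos + direction
            if np.linalg.norm(nxt - center) > limit:
                n = (pos - center) / max(np.linalg.norm(pos - center), 1e-9)
                direction = direction - 2.0 * np.dot(direction, n) * n
                direction /= np.linalg.norm(direction)
                nxt = pos + direction
                if np.linalg.norm(nxt - center) > limit:
                    nxt = pos  # stuck at the boundary; stay
            pos = nxt
            pts.append(pos.copy())
        branches.append(np.asarray(pts))
    return branches


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelVolume, AnnotationRecord]:
    """Build one phantom: intensity volume, label volume, annotation record.

    Labels: 0 background/shell, 1 vessel, 2 aneurysm.  Deterministic for
    a fixed ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.size
    center = np.full(3, (n - 1) / 2.0)

    zz, yy, xx = np.indices((n, n, n))
    dist = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    shell_outer = n / 2.0 - spec.shell_margin
    shell_inner = shell_outer - spec.shell_thickness
    shell = (dist >= shell_inner) & (dist <= shell_outer)

    r_vessel = rng.uniform(*spec.vessel_radius)
    interior = shell_inner - spec.moat
    limit = interior - r_vessel
    branches = _centerlines(spec, rng, limit, center)

    vessel = np.zeros((n, n, n), dtype=bool)
    for pts in branches:
        for p in pts:
            vessel[_ball_indices(p, r_vessel, n)] = True

    # aneurysms: spheres tangent to / overlapping a vessel wall
    aneurysm_masks: list[np.ndarray] = []
    aneurysm_radii: list[float] = []
    all_pts = np.vstack(branches)
    taken = np.zeros((n, n, n), dtype=bool)
    for _ in range(spec.n_aneurysms):
        placed = False
        for _attempt in range(200):
            r_a = rng.uniform(*spec.aneurysm_radius)
            p = all_pts[rng.integers(len(all_pts))]
            offset = _random_unit(rng)
            c_a = p + offset * (r_vessel + r_a - 1.0)
            if np.linalg.norm(c_a - center) + r_a > interior:
                continue
            mask = np.zeros((n, n, n), dtype=bool)
            mask[_ball_indices(c_a, r_a, n)] = True
            if (mask & taken).any():
                continue
            aneurysm_masks.append(mask)
            aneurysm_radii.append(r_a)
            taken |= mask
            placed = True
            break
        if not placed:
            raise RuntimeError("aneurysm placement failed after bounded retries")

    labels = np.zeros((n, n, n), dtype=np.int16)
    labels[vessel] = 1
    for mask in aneurysm_masks:
        labels[mask] = 2

    data = rng.normal(spec.background_mean, spec.background_sd, (n, n, n))
    bright = vessel | (labels == 2)
    data[bright] = rng.normal(spec.vessel_mu, spec.vessel_sigma, int(bright.sum()))
    data[shell] = spec.shell_intensity + rng.normal(0.0, 10.0, int(shell.sum()))
    data = np.clip(data, 0.0, None)

    if spec.bias_amplitude > 0:
        coarse = rng.normal(size=(4, 4, 4))
        field = ndimage.zoom(coarse, n / 4.0, order=3)
        field = field[:n, :n, :n]
        field = 1.0 + spec.bias_amplitude * field / max(np.abs(field).max(), 1e-9)
        data = data * field

    sp = (spec.spacing,) * 3
    vol = Volume(data.astype(np.float32), spacing=sp)
    lab = LabelVolume(labels, spacing=sp)

    aneurysms = [
        Aneurysm(
            voxels=np.argwhere(mask),
            max_diameter_mm=2.0 * r * spec.spacing,
            location=str(rng.choice(["ICA", "MCA", "ACA", "PCA"], p=[0.5, 0.2, 0.2, 0.1])),
        )
        for mask, r in zip(aneurysm_masks, aneurysm_radii)
    ]
    record = AnnotationRecord(
        case_id=f"phantom-{spec.rng_seed}",
        aneurysms=aneurysms,
        sex=str(rng.choice(["F", "M"], p=[0.63, 0.37])),
        age=float(np.clip(rng.normal(57.0, 14.0), 17, 90)),
        hypertension=bool(rng.random() < 0.5),
        spacing=sp,
        origin=(0.0, 0.0, 0.0),
    )
    return vol, lab, record


def _diameter_targets(n: int, quotas, rng: np.random.Generator) -> list[float]:
    """Target max-diameters (mm), optionally honouring per-bin quotas."""
    if quotas is None:
        return list(np.clip(rng.normal(6.5, 4.0, n), 2.0, 23.0))
    if sum(quotas) != n:
        raise ValueError("bin quotas must sum to the cohort size")
    targets = []
    for (lo, hi), count in zip(SIZE_BINS, quotas):
        lo_eff = max(lo, 2.0)
        hi_eff = min(hi, 23.0)
        targets.extend(rng.uniform(lo_eff, hi_eff, count))
    order = rng.permutation(n)
    return [float(targets[i]) for i in order]


def generate_cohort(
    n: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    size_bin_quotas: tuple[int, int, int, int] | None = None,
) -> list[tuple[Volume, LabelVolume, AnnotationRecord]]:
    """n phantoms with per-case jittered specs and cohort-like metadata.

    The voxel radius of each aneurysm stays in the spec's range while the
    per-case mm spacing is adjusted so the *physical* diameters span the
    requested size bins (or a broad, cohort-like spread by default).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    template = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    diameters = _diameter_targets(n, size_bin_quotas, rng)
    out = []
    for i, diam in enumerate(diameters):
        r_vox = rng.uniform(3.5, 5.5)
        case_spacing = diam / (2.0 * r_vox)
        case_seed = int((seed * 100003 + i * 7919) % (2**31 - 1))
        case_spec = replace(
            template,
            spacing=float(case_spacing),
            aneurysm_radius=(r_vox, r_vox),
            rng_seed=case_seed,
        )
        vol, lab, record = generate_phantom(case_spec)
        record.case_id = f"case-{i:03d}"
        out.append((vol, lab, record))
    return out
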