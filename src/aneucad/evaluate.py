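"""Lesion-detection evaluation: sphere/annotation matching, sensitivity,
false positives per case, cohort characterization and subgroup analysis.

The matching rule follows the sphere-marker output of the detector: a
detection sphere is a **true positive** iff strictly more than 30 % of
some annotated aneurysm's voxels fall inside it; an aneurysm counts as
**detected** if at least one detection makes it a true positive.  A
sphere capturing two aneurysms above the threshold is one TP detection
that marks both detected.  Overlap is always measured on the aneurysm's
side (fraction of the aneurysm inside the sphere), never the sphere's.

Sensitivity is reported to one decimal (percent), FPs/case to two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Aneurysm",
    "AnnotationRecord",
    "MatchResult",
    "EvalReport",
    "CohortSummary",
    "LOCATIONS",
    "SIZE_BINS",
    "match",
    "sensitivity",
    "fp_per_case",
    "subgroup_analysis",
    "summarize_cohort",
    "crossval_split",
    "evaluate_cases",
]

LOCATIONS = ("ICA", "MCA", "ACA", "PCA", "basilar", "vertebral")

#: Size bins in mm: [0, 3), [3, 5), [5, 10), [10, inf)
SIZE_BINS = ((0.0, 3.0), (3.0, 5.0), (5.0, 10.0), (10.0, np.inf))
SIZE_BIN_LABELS = ("<3.0", "3.0-4.9", "5.0-9.9", ">=10.0")

OVERLAP_THRESHOLD = 0.30  # strict: fraction must exceed this


def size_bin_label(diameter_mm: float) -> str:
    for (lo, hi), lab in zip(SIZE_BINS, SIZE_BIN_LABELS):
        if lo <= diameter_mm < hi:
            return lab
    raise ValueError(f"invalid diameter {diameter_mm}")


@dataclass
class Aneurysm:
    """One annotated aneurysm: its voxels (original grid) and metadata."""

    voxels: np.ndarray  # (n, 3) integer voxel indices
    max_diameter_mm: float
    location: str = "ICA"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)
        if self.max_diameter_mm <= 0:
            raise ValueError("diameter must be > 0")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")


@dataclass
class AnnotationRecord:
    """Ground truth and patient metadata for one case."""

    case_id: str
    aneurysms: list[Aneurysm] = field(default_factory=list)
    sex: str = "F"  # "F" | "M"
    age: float = 57.0
    hypertension: bool = False
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class MatchResult:
    """Verdicts for one case."""

    case_id: str
    detection_verdicts: list[str]  # "TP" | "FP" per detection
    aneurysm_detected: list[bool]  # per aneurysm
    overlap_fractions: np.ndarray  # (n_detections, n_aneurysms)

    @property
    def n_tp(self) -> int:
        return sum(v == "TP" for v in self.detection_verdicts)

    @property
    def n_fp(self) -> int:
        return sum(v == "FP" for v in self.detection_verdicts)


@dataclass
class EvalReport:
    sensitivity_pct: float
    fp_per_case: float
    n_cases: int
    n_aneurysms: int
    n_detected: int
    n_fp: int
    subgroups: pd.DataFrame | None = None


@dataclass
class CohortSummary:
    n_patients: int
    n_male: int
    n_female: int
    age_mean: float
    age_sd: float
    n_hypertension: int
    hypertension_pct: float
    n_aneurysms: int
    size_mean: float
    size_sd: float
    size_bin_counts: dict[str, int]
    location_counts: dict[str, int]


def _detection_world(det, record: AnnotationRecord):
    """Sphere centre (mm) and radius (mm) of a detection in record space."""
    center = np.asarray(getattr(det, "center_mm"), dtype=float)
    radius = float(getattr(det, "radius_mm"))
    return center, radius


def match(detections, record: AnnotationRecord) -> MatchResult:
    """Apply the strict >30 % aneurysm-in-sphere rule to one case."""
    spacing = np.asarray(record.spacing, dtype=float)
    origin = np.asarray(record.origin, dtype=float)
    n_det, n_ane = len(detections), len(record.aneurysms)
    fractions = np.zeros((n_det, n_ane))
    for d, det in enumerate(detections):
        center, radius = _detection_world(det, record)
        for a, ane in enumerate(record.aneurysms):
            world = origin + ane.voxels * spacing
            inside = np.linalg.norm(world - center, axis=1) <= radius
            fractions[d, a] = inside.mean() if len(inside) else 0.0
    hits = fractions > OVERLAP_THRESHOLD
    verdicts = ["TP" if n_ane and hits[d].any() else "FP" for d in range(n_det)]
    detected = [bool(hits[:, a].any()) if n_det else False for a in range(n_ane)]
    return MatchResult(record.case_id, verdicts, detected, fractions)


def sensitivity(results: list[MatchResult]) -> float:
    """Detected aneurysms / total aneurysms, as a percent (1 decimal)."""
    total = sum(len(r.aneurysm_detected) for r in results)
    if total == 0:
        raise ValueError("no aneurysms to evaluate")
    detected = sum(sum(r.aneurysm_detected) for r in results)
    return round(100.0 * detected / total, 1)


def fp_per_case(results: list[MatchResult]) -> float:
    """Mean false-positive detections per case (2 decimals)."""
    if not results:
        raise ValueError("no cases to evaluate")
    return round(sum(r.n_fp for r in results) / len(results), 2)


def _stratum_sensitivity(flags: list[bool]) -> float | None:
    if not flags:
        return None
    return round(100.0 * sum(flags) / len(flags), 1)


def subgroup_analysis(
    results: list[MatchResult], records: list[AnnotationRecord]
) -> pd.DataFrame:
    """Per-stratum sensitivity for sex, age band, hypertension, size, location.

    Empty strata are reported with sensitivity ``NaN`` (undefined), not 0.
    """
    by_id = {r.case_id: r for r in results}
    rows: list[dict] = []
    per_ane: list[dict] = []
    for rec in records:
        res = by_id.get(rec.case_id)
        if res is None:
            raise ValueError(f"no match result for case {rec.case_id}")
        if len(res.aneurysm_detected) != len(rec.aneurysms):
            raise ValueError(f"aneurysm count mismatch for case {rec.case_id}")
        for ane, det in zip(rec.aneurysms, res.aneurysm_detected):
            per_ane.append(
                {
                    "detected": bool(det),
                    "sex": rec.sex,
                    "age_band": "<60" if rec.age < 60 else ">=60",
                    "hypertension": "yes" if rec.hypertension else "no",
                    "size_bin": size_bin_label(ane.max_diameter_mm),
                    "location": ane.location,
                }
            )
    df = pd.DataFrame(per_ane)
    axes = {
        "sex": ("F", "M"),
        "age_band": ("<60", ">=60"),
        "hypertension": ("yes", "no"),
        "size_bin": SIZE_BIN_LABELS,
        "location": LOCATIONS,
    }
    for axis, strata in axes.items():
        for stratum in strata:
            sub = df[df[axis] == stratum] if len(df) else df
            flags = list(sub["detected"]) if len(sub) else []
            rows.append(
                {
                    "axis": axis,
                    "stratum": stratum,
                    "n_aneurysms": len(flags),
                    "n_detected": int(sum(flags)),
                    "sensitivity_pct": _stratum_sensitivity(flags),
                }
            )
    return pd.DataFrame(rows)


def summarize_cohort(records: list[AnnotationRecord]) -> CohortSummary:
    """Patient- and aneurysm-level characterization of a cohort."""
    if not records:
        raise ValueError("empty cohort")
    diameters = [a.max_diameter_mm for r in records for a in r.aneurysms]
    if any(d is None for d in diameters):
        raise ValueError("missing diameters")
    ages = np.array([r.age for r in records], dtype=float)
    bins = {lab: 0 for lab in SIZE_BIN_LABELS}
    locs = {loc: 0 for loc in LOCATIONS}
    for r in records:
        for a in r.aneurysms:
            bins[size_bin_label(a.max_diameter_mm)] += 1
            locs[a.location] += 1
    n_htn = sum(r.hypertension for r in records)
    diam = np.asarray(diameters, dtype=float)
    return CohortSummary(
        n_patients=len(records),
        n_male=sum(r.sex == "M" for r in records),
        n_female=sum(r.sex == "F" for r in records),
        age_mean=float(ages.mean()),
        age_sd=float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
        n_hypertension=int(n_htn),
        hypertension_pct=round(100.0 * n_htn / len(records), 1),
        n_aneurysms=len(diameters),
        size_mean=float(diam.mean()) if len(diam) else float("nan"),
        size_sd=float(diam.std(ddof=1)) if len(diam) > 1 else 0.0,
        size_bin_counts=bins,
        location_counts=locs,
    )


def crossval_split(cases: list, k: int = 5, seed: int = 0) -> list[tuple[list, list]]:
    """k disjoint folds (sizes within 1) as (train, validation) pairs."""
    if len(cases) < k:
        raise ValueError(f"need at least {k} cases for {k}-fold split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        val = [cases[j] for j in folds[i]]
        train = [cases[j] for f in folds[:i] + folds[i + 1 :] for j in f]
        out.append((train, val))
    return out


def evaluate_cases(
    per_case_detections: dict[str, list], records: list[AnnotationRecord]
) -> tuple[EvalReport, list[MatchResult]]:
    """Match every case and assemble the full evaluation report."""
    results = [match(per_case_detections.get(r.case_id, []), r) for r in records]
    total = sum(len(r.aneurysm_detected) for r in results)
    detected = sum(sum(r.aneurysm_detected) for r in results)
    report = EvalReport(
        sensitivity_pct=sensitivity(results) if total else float("nan"),
        fp_per_case=fp_per_case(results),
        n_cases=len(records),
        n_aneurysms=total,
        n_detected=int(detected),
        n_fp=sum(r.n_fp for r in results),
        subgroups=subgroup_analysis(results, records) if total else None,
    )
    return report, results
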