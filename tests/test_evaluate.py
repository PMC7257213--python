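import numpy as np
import pytest

from aneucad.detect import Detection
from aneucad.evaluate import (
    Aneurysm,
    AnnotationRecord,
    crossval_split,
    evaluate_cases,
    fp_per_case,
    match,
    sensitivity,
    subgroup_analysis,
    summarize_cohort,
)


def _det(center, radius):
    return Detection(
        center_index=tuple(int(round(c)) for c in center),
        center_mm=tuple(float(c) for c in center),
        radius_vox=float(radius),
        radius_mm=float(radius),
        score=0.9,
        component_voxels=10,
    )


def _line_aneurysm(n=100, diameter=6.0, location="ICA"):
    voxels = np.array([(0, 0, x) for x in range(n)])
    return Aneurysm(voxels=voxels, max_diameter_mm=diameter, location=location)


class TestMatch:
    def test_just_above_30pct_is_tp(self):
        rec = AnnotationRecord("c", [_line_aneurysm(100)])
        res = match([_det((0, 0, 0), 30.2)], rec)  # covers voxels x=0..30 -> 31 %
        assert res.detection_verdicts == ["TP"]
        assert res.aneurysm_detected == [True]

    def test_exactly_30pct_is_fp(self):
        rec = AnnotationRecord("c", [_line_aneurysm(100)])
        res = match([_det((0, 0, 0), 29.5)], rec)  # covers x=0..29 -> exactly 30 %
        assert res.overlap_fractions[0, 0] == pytest.approx(0.30)
        assert res.detection_verdicts == ["FP"]
        assert res.aneurysm_detected == [False]

    def test_no_detections_one_missed(self):
        rec = AnnotationRecord("c", [_line_aneurysm(10)])
        res = match([], rec)
        assert res.n_tp == 0 and res.n_fp == 0
        assert res.aneurysm_detected == [False]

    def test_one_sphere_covering_two_aneurysms_marks_both(self):
        a1 = Aneurysm(np.array([(0, 0, 0), (0, 0, 1)]), 4.0)
        a2 = Aneurysm(np.array([(0, 1, 0), (0, 1, 1)]), 4.0)
        rec = AnnotationRecord("c", [a1, a2])
        res = match([_det((0, 0.5, 0.5), 2.0)], rec)
        assert res.detection_verdicts == ["TP"]
        assert res.aneurysm_detected == [True, True]

    def test_verdict_partition_exhaustive(self, rng):
        rec = AnnotationRecord("c", [_line_aneurysm(20)])
        dets = [_det(rng.uniform(0, 20, 3), rng.uniform(1, 8)) for _ in range(7)]
        res = match(dets, rec)
        assert res.n_tp + res.n_fp == len(dets)
        assert len(res.aneurysm_detected) == 1

    def test_agrees_with_brute_force_membership_count(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_vox = rng.integers(5, 40)
            voxels = rng.integers(0, 16, (n_vox, 3))
            voxels = np.unique(voxels, axis=0)
            spacing = tuple(rng.uniform(0.5, 2.0, 3))
            rec = AnnotationRecord(
                "c", [Aneurysm(voxels, 5.0)], spacing=spacing
            )
            center = rng.uniform(0, 16, 3) * np.asarray(spacing)
            radius = rng.uniform(1, 12)
            res = match([_det(center, radius)], rec)
            # independent brute force: loop voxel by voxel in world space
            inside = 0
            for v in voxels:
                w = np.asarray(v) * np.asarray(spacing)
                if np.sqrt(((w - center) ** 2).sum()) <= radius:
                    inside += 1
            frac = inside / len(voxels)
            assert res.overlap_fractions[0, 0] == pytest.approx(frac)
            assert (res.detection_verdicts[0] == "TP") == (frac > 0.30)


class TestRates:
    def test_29_of_35_prints_82_9(self):
        results = [_mk_result(f"c{i}", True, 0) for i in range(29)]
        results += [_mk_result(f"m{i}", False, 0) for i in range(6)]
        assert sensitivity(results) == 82.9

    def test_sensitivity_bounds(self):
        assert sensitivity([_mk_result("a", False, 0)]) == 0.0
        assert sensitivity([_mk_result("a", True, 0)] * 5) == 100.0

    def test_sensitivity_invariant_to_ordering(self, rng):
        results = [_mk_result(f"c{i}", bool(rng.random() < 0.6), 0) for i in range(20)]
        shuffled = list(results)
        rng.shuffle(shuffled)
        assert sensitivity(results) == sensitivity(shuffled)

    def test_zero_aneurysms_rejected(self):
        empty = _mk_result("c", None, 0)
        with pytest.raises(ValueError):
            sensitivity([empty])

    @pytest.mark.parametrize(
        "fps,cases,expected", [(0, 10, 0.0), (7, 2, 3.5), (1, 3, 0.33)]
    )
    def test_fp_per_case_rounding(self, fps, cases, expected):
        results = [_mk_result(f"c{i}", True, fps if i == 0 else 0) for i in range(cases)]
        assert fp_per_case(results) == expected


def _mk_result(case_id, detected, n_fp):
    from aneucad.evaluate import MatchResult

    if detected is None:
        flags = []
    else:
        flags = [bool(detected)]
    verdicts = ["TP"] * (1 if detected else 0) + ["FP"] * n_fp
    return MatchResult(case_id, verdicts, flags, np.zeros((len(verdicts), len(flags))))


class TestSubgroups:
    def _cohort(self):
        records, results = [], []
        plan = [
            # case_id, sex, age, htn, diameter, location, detected
            ("a", "F", 45, True, 12.0, "ICA", True),
            ("b", "M", 70, False, 11.0, "MCA", True),
            ("c", "F", 62, True, 4.0, "ACA", False),
            ("d", "M", 50, False, 2.5, "PCA", True),
        ]
        for cid, sex, age, htn, diam, loc, det in plan:
            records.append(
                AnnotationRecord(cid, [_line_aneurysm(10, diam, loc)], sex=sex,
                                 age=age, hypertension=htn)
            )
            results.append(_mk_result(cid, det, 0))
        return records, results

    def test_table_matches_hand_count(self):
        records, results = self._cohort()
        table = subgroup_analysis(results, records)
        get = lambda axis, s: table[(table.axis == axis) & (table.stratum == s)].iloc[0]
        assert get("size_bin", ">=10.0").sensitivity_pct == 100.0
        assert get("size_bin", "3.0-4.9").sensitivity_pct == 0.0
        assert get("sex", "F").sensitivity_pct == 50.0
        assert get("age_band", ">=60").sensitivity_pct == 50.0
        assert get("hypertension", "yes").sensitivity_pct == 50.0

    def test_empty_stratum_is_undefined_not_zero(self):
        records, results = self._cohort()
        table = subgroup_analysis(results, records)
        basilar = table[(table.axis == "location") & (table.stratum == "basilar")]
        assert basilar.iloc[0].n_aneurysms == 0
        assert basilar.iloc[0].sensitivity_pct is None or np.isnan(
            basilar.iloc[0].sensitivity_pct
        )

    def test_stratum_weighted_recomposition(self):
        records, results = self._cohort()
        table = subgroup_analysis(results, records)
        overall = sensitivity(results)
        sexes = table[table.axis == "sex"]
        weighted = (sexes.n_detected.sum() / sexes.n_aneurysms.sum()) * 100
        assert round(weighted, 1) == overall


class TestCohortSummary:
    def _table1_records(self):
        """35 patients / 35 aneurysms shaped like the external test set."""
        diam_by_bin = {"<3.0": 2.5, "3.0-4.9": 4.0, "5.0-9.9": 7.0, ">=10.0": 12.0}
        bins = [("<3.0", 2), ("3.0-4.9", 11), ("5.0-9.9", 17), (">=10.0", 5)]
        locations = ["ICA"] * 19 + ["MCA"] * 5 + ["ACA"] * 8 + ["PCA"] * 3
        diams = [diam_by_bin[lab] for lab, cnt in bins for _ in range(cnt)]
        records = []
        for i, (d, loc) in enumerate(zip(diams, locations)):
            records.append(
                AnnotationRecord(
                    f"c{i}",
                    [_line_aneurysm(5, d, loc)],
                    sex="M" if i < 13 else "F",
                    age=57,
                    hypertension=i < 18,
                )
            )
        return records

    def test_bin_counts_total_35(self):
        s = summarize_cohort(self._table1_records())
        assert s.n_aneurysms == 35
        assert s.size_bin_counts == {"<3.0": 2, "3.0-4.9": 11, "5.0-9.9": 17,
                                     ">=10.0": 5}
        assert s.location_counts["ICA"] == 19
        assert sum(s.location_counts.values()) == 35

    def test_hypertension_percentage(self):
        s = summarize_cohort(self._table1_records())
        assert s.n_hypertension == 18
        assert s.hypertension_pct == 51.4

    def test_single_patient_single_bin(self):
        r = AnnotationRecord("x", [_line_aneurysm(5, 4.0)])
        s = summarize_cohort([r])
        assert s.size_bin_counts == {"<3.0": 0, "3.0-4.9": 1, "5.0-9.9": 0,
                                     ">=10.0": 0}

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])


class TestCrossval:
    def test_20_cases_5_folds_of_4(self):
        folds = crossval_split(list(range(20)), k=5, seed=0)
        assert len(folds) == 5
        for train, val in folds:
            assert len(val) == 4 and len(train) == 16
            assert set(train) | set(val) == set(range(20))

    def test_deterministic_under_seed(self):
        a = crossval_split(list(range(13)), k=5, seed=9)
        b = crossval_split(list(range(13)), k=5, seed=9)
        assert a == b

    def test_fewer_cases_than_folds_rejected(self):
        with pytest.raises(ValueError):
            crossval_split([1, 2, 3], k=5)


class TestEvaluateCases:
    def test_partition_identity(self):
        rec = AnnotationRecord("c", [_line_aneurysm(100)])
        dets = [_det((0, 0, 0), 40.0), _det((90, 90, 90), 2.0)]
        report, results = evaluate_cases({"c": dets}, [rec])
        assert report.n_detected + sum(
            1 for r in results for d in r.aneurysm_detected if not d
        ) == report.n_aneurysms
        assert report.n_fp == 1
        assert report.sensitivity_pct == 100.0
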