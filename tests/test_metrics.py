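"""Surface/overlap metrics against hand-derived cases and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mcmunet import (
    EmptyMaskError,
    LabelMask,
    annotation_cc,
    assd,
    case_metrics,
    dsc,
    evaluate_cases,
    extract_boundary,
    hd95,
    jaccard,
    pooled_overlap,
)
from mcmunet.data import Volume, write_volume
from mcmunet.metrics import MetricReport

from conftest import brute_assd, brute_boundary, brute_hausdorff, brute_hd95, random_mask


def _single_voxel(pos, shape=(10, 10, 10)):
    m = np.zeros(shape, np.uint8)
    m[pos] = 1
    return m


class TestBoundaryExtraction:
    def test_single_voxel_is_its_own_boundary(self):
        b = extract_boundary(_single_voxel((4, 4, 4)))
        assert b.tolist() == [[4, 4, 4]]

    def test_solid_cube_boundary_is_shell(self):
        m = np.zeros((5, 5, 5), np.uint8)
        m[1:4, 1:4, 1:4] = 1
        b = extract_boundary(m)
        assert len(b) == 26  # all 27 cube voxels except the centre
        assert [2, 2, 2] not in b.tolist()

    def test_full_grid_boundary_is_outer_faces(self):
        m = np.ones((4, 5, 6), np.uint8)
        b = {tuple(v) for v in extract_boundary(m)}
        interior = {(x, y, z) for x in range(1, 3) for y in range(1, 4)
                    for z in range(1, 5)}
        assert b == {tuple(v) for v in np.argwhere(m)} - interior

    def test_empty_mask_signals_no_surface(self):
        with pytest.raises(EmptyMaskError):
            extract_boundary(np.zeros((3, 3, 3), np.uint8))

    def test_matches_hand_enumeration_on_random_masks(self, rng):
        for _ in range(20):
            m = random_mask(rng, (7, 6, 5))
            got = extract_boundary(m)
            want = brute_boundary(m)
            assert np.array_equal(np.array(sorted(got.tolist())), want)


class TestSurfaceDistances:
    def test_identical_masks_have_zero_distance(self, rng):
        m = random_mask(rng, (8, 8, 8))
        assert assd(m, m) == 0.0
        assert hd95(m, m) == 0.0

    def test_single_voxels_five_apart(self):
        a = _single_voxel((2, 3, 3))
        b = _single_voxel((7, 3, 3))
        assert assd(a, b) == pytest.approx(5.0, abs=1e-12)
        assert hd95(a, b) == pytest.approx(5.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            shape = tuple(rng.integers(4, 9, 3))
            a, b = random_mask(rng, shape), random_mask(rng, shape)
            assert assd(a, b) == pytest.approx(brute_assd(a, b), abs=1e-9)
            assert hd95(a, b) == pytest.approx(brute_hd95(a, b), abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_mask(rng, (8, 8, 4)), random_mask(rng, (8, 8, 4))
            assert assd(a, b) == assd(b, a)
            assert hd95(a, b) == hd95(b, a)

    def test_hd95_bounded_by_exact_hausdorff(self, rng):
        for _ in range(10):
            a, b = random_mask(rng, (9, 7, 5)), random_mask(rng, (9, 7, 5))
            assert hd95(a, b) <= brute_hausdorff(a, b) + 1e-12

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            assd(np.zeros((3, 3, 3), np.uint8), _single_voxel((1, 1, 1), (3, 3, 3)))

    def test_mm_units_scale_with_spacing(self):
        a = LabelMask(_single_voxel((2, 3, 3)), spacing=(0.66, 0.66, 5.0))
        b = LabelMask(_single_voxel((7, 3, 3)), spacing=(0.66, 0.66, 5.0))
        assert assd(a, b, units="mm") == pytest.approx(5 * 0.66)
        assert assd(a, b, units="voxel") == pytest.approx(5.0)


class TestOverlapMetrics:
    def test_identical_masks(self, rng):
        m = random_mask(rng, (6, 6, 3))
        assert jaccard(m, m) == 100.0
        assert dsc(m, m) == 100.0

    def test_disjoint_masks(self):
        a = _single_voxel((0, 0, 0), (4, 4, 1))
        b = _single_voxel((3, 3, 0), (4, 4, 1))
        assert jaccard(a, b) == 0.0
        assert dsc(a, b) == 0.0

    def test_hand_counted_toy_masks(self):
        # 2x2x1 grid: A = {(0,0),(0,1),(1,0)}, B = {(0,0),(0,1),(1,1)}
        a = np.zeros((2, 2, 1), np.uint8)
        b = np.zeros((2, 2, 1), np.uint8)
        a[0, 0, 0] = a[0, 1, 0] = a[1, 0, 0] = 1
        b[0, 0, 0] = b[0, 1, 0] = b[1, 1, 0] = 1
        assert jaccard(a, b) == pytest.approx(50.0)          # |A^B|=2, |AvB|=4
        assert dsc(a, b) == pytest.approx(100 * 2 * 2 / (1 + 1 + 4))

    def test_dice_jaccard_identity(self, rng):
        for _ in range(20):
            a, b = random_mask(rng, (8, 8, 4)), random_mask(rng, (8, 8, 4))
            j, d = jaccard(a, b), dsc(a, b)
            assert d == pytest.approx(200 * j / (100 + j), abs=1e-9)
            assert j <= d <= 100.0

    def test_both_empty_raises(self):
        z = np.zeros((3, 3, 3), np.uint8)
        with pytest.raises(EmptyMaskError):
            jaccard(z, z)
        with pytest.raises(EmptyMaskError):
            dsc(z, z)


_mask_strategy = arrays(np.uint8, (5, 5, 3), elements=st.integers(0, 1)).filter(
    lambda m: m.sum() > 0)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(a=_mask_strategy, b=_mask_strategy)
def test_metric_properties_hold_on_arbitrary_masks(a, b):
    """Symmetry of the surface distances and the Dice-Jaccard identity."""
    assert assd(a, b) == assd(b, a)
    assert hd95(a, b) == hd95(b, a)
    j, d = jaccard(a, b), dsc(a, b)
    assert d == pytest.approx(200 * j / (100 + j), abs=1e-9)
    assert 0.0 <= j <= d <= 100.0


def test_translation_leaves_all_metrics_unchanged(rng):
    a = random_mask(rng, (8, 8, 6))
    b = random_mask(rng, (8, 8, 6))
    big_a = np.zeros((14, 14, 12), np.uint8)
    big_b = np.zeros((14, 14, 12), np.uint8)
    big_a[:8, :8, :6], big_b[:8, :8, :6] = a, b
    shift_a = np.roll(np.roll(np.roll(big_a, 3, 0), 2, 1), 4, 2)
    shift_b = np.roll(np.roll(np.roll(big_b, 3, 0), 2, 1), 4, 2)
    for fn in (assd, hd95, jaccard, dsc):
        assert fn(big_a, big_b) == pytest.approx(fn(shift_a, shift_b), abs=1e-12)


class TestAnnotationAgreement:
    def test_perfect_agreement(self):
        assert annotation_cc([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert annotation_cc([1, 2, 3], [-1 + 10, -2 + 10, -3 + 10]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert annotation_cc([1, 2, 3], [2, 4, 5]) == pytest.approx(0.98198, abs=1e-4)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            annotation_cc([1, 1, 1], [1, 2, 3])


class TestCaseEvaluation:
    @staticmethod
    def _write_mask(path, grid):
        write_volume(Volume(grid.astype(np.uint8), (1.0, 1.0, 1.0)), path)

    def test_identical_predictions_score_perfectly(self, tmp_path, rng):
        gt_dir, pr_dir = tmp_path / "gt", tmp_path / "pred"
        for i in range(3):
            m = random_mask(rng, (8, 8, 4))
            self._write_mask(gt_dir / f"case{i}.nii.gz", m)
            self._write_mask(pr_dir / f"case{i}.nii.gz", m)
        report = evaluate_cases(pr_dir, gt_dir)
        assert (report.per_case["dsc_pct"] == 100.0).all()
        assert (report.per_case["assd_voxel"] == 0.0).all()

    def test_empty_prediction_policy(self, tmp_path, rng):
        gt_dir, pr_dir = tmp_path / "gt", tmp_path / "pred"
        m = random_mask(rng, (6, 6, 3))
        self._write_mask(gt_dir / "a.nii.gz", m)
        self._write_mask(pr_dir / "a.nii.gz", np.zeros_like(m))
        self._write_mask(gt_dir / "b.nii.gz", m)
        self._write_mask(pr_dir / "b.nii.gz", m)
        with pytest.warns(UserWarning, match="empty prediction"):
            report = evaluate_cases(pr_dir, gt_dir)
        row = report.per_case.set_index("case_id").loc["a"]
        assert row["dsc_pct"] == 0.0 and np.isnan(row["assd_voxel"])
        # distances from the empty case are excluded from aggregate means
        assert report.aggregate["assd_voxel"] == 0.0
        assert report.aggregate["dsc_pct"] == 50.0

    def test_aggregate_is_arithmetic_mean(self, tmp_path, rng):
        gt_dir, pr_dir = tmp_path / "gt", tmp_path / "pred"
        vals = []
        for i in range(3):
            gt = random_mask(rng, (8, 8, 4))
            pr = random_mask(rng, (8, 8, 4))
            self._write_mask(gt_dir / f"c{i}.nii.gz", gt)
            self._write_mask(pr_dir / f"c{i}.nii.gz", pr)
            vals.append(dsc(LabelMask(pr), LabelMask(gt)))
        report = evaluate_cases(pr_dir, gt_dir)
        assert report.aggregate["dsc_pct"] == pytest.approx(np.mean(vals))

    def test_missing_prediction_lists_the_case(self, tmp_path, rng):
        gt_dir, pr_dir = tmp_path / "gt", tmp_path / "pred"
        self._write_mask(gt_dir / "only_gt.nii.gz", random_mask(rng, (5, 5, 2)))
        pr_dir.mkdir()
        with pytest.raises(FileNotFoundError, match="only_gt"):
            evaluate_cases(pr_dir, gt_dir)

    def test_report_csv_roundtrip(self, tmp_path, rng):
        rows = [{"case_id": "x", "assd_voxel": 0.5, "hd95_voxel": 1.0,
                 "jaccard_pct": 80.0, "dsc_pct": 88.9}]
        report = MetricReport(pd.DataFrame(rows, columns=MetricReport.COLUMNS))
        report.to_csv(tmp_path / "r.csv")
        back = pd.read_csv(tmp_path / "r.csv")
        assert list(back["case_id"]) == ["x", "mean"]
        assert back["dsc_pct"].iloc[1] == pytest.approx(88.9)


def test_pooled_overlap_weights_by_voxel_counts(rng):
    big = random_mask(rng, (12, 12, 6))
    small = random_mask(rng, (4, 4, 2))
    pairs = [(LabelMask(big), LabelMask(big)), (LabelMask(small), LabelMask(np.ones_like(small)))]
    pooled = pooled_overlap(pairs)
    per_case = np.mean([100.0, dsc(small, np.ones_like(small))])
    assert pooled["dsc_pct"] > per_case  # the perfect big case dominates pooling


def test_case_metrics_requires_nonempty_ground_truth(rng):
    with pytest.raises(EmptyMaskError):
        case_metrics(LabelMask(random_mask(rng, (4, 4, 2))),
                     LabelMask(np.zeros((4, 4, 2), np.uint8)))
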