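"""Metric-suite unit and property tests against the brute-force oracle."""

import numpy as np
import pytest

from fractalseg.metrics import (
    BinaryMask,
    ConfusionCounts,
    UndefinedMetricError,
    asd,
    confusion,
    dice,
    directed_hd,
    evaluate_pair,
    extract_surface,
    hausdorff,
    hd95,
    precision,
    recall,
    rvd,
    voe,
)

from .conftest import mask
from .oracle import brute_force_metrics


def random_mask_pair(rng, max_side=32, spacing=(1.0, 1.0)):
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    density = rng.uniform(0.05, 0.6)
    pm = (rng.random((h, w)) < density).astype(np.uint8)
    gt = (rng.random((h, w)) < density).astype(np.uint8)
    return BinaryMask(pm, spacing), BinaryMask(gt, spacing)


class TestOverlapMetrics:
    def test_dice_identity_disjoint_and_counts(self):
        m = mask(["##.", ".#.", "..."])
        assert dice(m, m) == 100.0
        a = mask(["#..", "...", "..."])
        b = mask(["..#", "...", "..."])
        assert dice(a, b) == 0.0
        # |PM|=3, |GT|=4, overlap 2
        pm = mask(["###.", "....", "...."])
        gt = mask([".###", "...#", "...."])
        assert dice(pm, gt) == pytest.approx(200 * 2 / 7)
        assert dice(gt, pm) == dice(pm, gt)

    def test_dice_both_empty_is_perfect_by_convention(self):
        e = mask(["...", "..."])
        assert dice(e, e) == 100.0
        assert evaluate_pair(e, e).degenerate_flag

    def test_voe_is_one_minus_jaccard(self):
        pm = mask(["###.", "....", "...."])
        gt = mask([".###", "...#", "...."])
        # intersection 2, union 5
        assert voe(pm, gt) == pytest.approx(60.0)
        m = mask(["##", ".."])
        assert voe(m, m) == 0.0
        a = mask(["#.", ".."])
        b = mask([".#", ".."])
        assert voe(a, b) == 100.0

    def test_rvd_sign_and_errors(self):
        six = mask(["###", "###"])
        four = mask(["##.", "##."])
        assert rvd(six, four) == pytest.approx(50.0)
        assert rvd(four, six) == pytest.approx(-100 / 3)
        two = mask(["#..", "#.."])
        assert rvd(two, four) == pytest.approx(-50.0)
        assert rvd(four, four) == 0.0
        with pytest.raises(UndefinedMetricError):
            rvd(four, mask(["...", "..."]))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            dice(mask(["#"]), mask(["##"]))


class TestSurfaceExtraction:
    def test_single_pixel_and_empty(self):
        s = extract_surface(mask(["#"]))
        assert s.points.tolist() == [[0, 0]]
        assert len(extract_surface(mask(["..", ".."]))) == 0

    def test_filled_square_perimeter(self):
        m = mask(["#####", "#####", "#####", "#####", "#####"])
        s = extract_surface(m)
        # 5x5 square: 16 perimeter pixels (image border counts as boundary)
        assert len(s) == 16
        interior = {(r, c) for r in range(1, 4) for c in range(1, 4)}
        assert not interior & set(map(tuple, s.points.tolist()))

    def test_border_pixels_count_as_boundary(self):
        m = mask(["###", "###", "###"])
        assert len(extract_surface(m)) == 8  # all but the centre


class TestSurfaceDistances:
    def test_asd_identity_and_offset(self):
        m = mask(["..", "#."])
        assert asd(m, m) == 0.0
        a = mask(["#...", "...."])
        b = mask(["...#", "...."])
        assert asd(a, b) == pytest.approx(3.0)
        aniso_a = BinaryMask(a.grid, (1.0, 0.5))
        aniso_b = BinaryMask(b.grid, (1.0, 0.5))
        assert asd(aniso_a, aniso_b) == pytest.approx(1.5)

    def test_directed_hd_pythagoras_and_asymmetry(self):
        a = extract_surface(mask(["#....", ".....", ".....", ".....", "....."]))
        b = extract_surface(mask([".....", ".....", ".....", ".....", "....#"]))
        assert directed_hd(a, b) == pytest.approx(np.hypot(4, 4))
        one = extract_surface(mask(["#........."]))
        two = extract_surface(mask(["#........#"]))
        assert directed_hd(one, two) == 0.0
        assert directed_hd(two, one) == 9.0
        with pytest.raises(UndefinedMetricError):
            directed_hd(one, extract_surface(mask(["...."])))

    def test_hd_translation_of_square(self):
        a = np.zeros((12, 12), np.uint8)
        a[3:7, 2:6] = 1
        b = np.zeros((12, 12), np.uint8)
        b[3:7, 5:9] = 1  # shifted 3 columns
        assert hausdorff(BinaryMask(a), BinaryMask(b)) == pytest.approx(3.0)

    def test_hd95_damps_single_outlier(self):
        # a line of coincident boundary plus one distant outlier
        a = np.zeros((3, 40), np.uint8)
        b = np.zeros((3, 40), np.uint8)
        a[1, :21] = 1
        b[1, :21] = 1
        a[1, 30] = 1  # outlier 10 px from the shared segment end
        ma, mb = BinaryMask(a), BinaryMask(b)
        assert hausdorff(ma, mb) == pytest.approx(10.0)
        assert hd95(ma, mb) < hausdorff(ma, mb)

    def test_empty_mask_penalty_is_image_diagonal(self):
        full = mask(["##", "##"])
        empty = mask(["..", ".."])
        assert asd(full, empty) == pytest.approx(np.hypot(2, 2))
        assert hausdorff(full, empty) == pytest.approx(np.hypot(2, 2))
        assert asd(empty, empty) == 0.0


class TestDetectionMetrics:
    def test_confusion_counts(self):
        pm = mask(["####", "...."])
        gt = mask(["..##", "##.."])
        c = confusion(pm, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 2, 2, 2)
        assert c.tp + c.fp + c.fn + c.tn == 8
        same = mask(["#.#", "..."])
        c2 = confusion(same, same)
        assert (c2.tp, c2.fp, c2.fn) == (2, 0, 0)
        c3 = confusion(mask(["..."]), mask(["##."]))
        assert (c3.tp, c3.fn) == (0, 2)

    def test_recall_precision(self):
        assert recall(ConfusionCounts(2, 0, 2, 10)) == 50.0
        assert precision(ConfusionCounts(2, 0, 2, 10)) == 100.0
        assert recall(ConfusionCounts(0, 3, 5, 1)) == 0.0
        with pytest.raises(UndefinedMetricError):
            recall(ConfusionCounts(0, 1, 0, 1))
        with pytest.raises(UndefinedMetricError):
            precision(ConfusionCounts(0, 0, 1, 1))


class TestEvaluatePair:
    def test_perfect_prediction_row(self):
        m = mask([".##.", ".##.", "...."])
        r = evaluate_pair(m, m)
        assert (r.dsc, r.voe, r.rvd, r.asd, r.hd, r.hd95, r.rec, r.pre) == (
            100.0, 0.0, 0.0, 0.0, 0.0, 0.0, 100.0, 100.0)
        assert not r.degenerate_flag

    def test_empty_prediction_convention(self):
        gt = mask([".##.", "....", "...."])
        pm = mask(["....", "....", "...."])
        r = evaluate_pair(pm, gt)
        assert r.dsc == 0.0 and r.voe == 100.0 and r.rec == 0.0 and r.pre == 0.0
        assert r.asd == pytest.approx(gt.diagonal_mm)
        assert r.degenerate_flag

    def test_partial_overlap_row(self):
        pm = mask(["###.", "....", "...."])
        gt = mask([".###", "...#", "...."])
        r = evaluate_pair(pm, gt)
        assert r.dsc == pytest.approx(400 / 7)
        assert r.voe == pytest.approx(60.0)
        assert r.rvd == pytest.approx(-25.0)


class TestMetricProperties:
    """Invariants on arbitrary masks via hypothesis (derandomized)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    grids = hnp.arrays(np.uint8, hnp.array_shapes(min_dims=2, max_dims=2,
                                                  min_side=2, max_side=12),
                       elements=st.integers(0, 1))

    @given(g=grids)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_identity_scores_on_any_mask(self, g):
        m = BinaryMask(g)
        if m.volume == 0:
            assert dice(m, m) == 100.0  # empty-vs-empty convention
            return
        assert dice(m, m) == 100.0
        assert voe(m, m) == 0.0
        assert rvd(m, m) == 0.0
        assert asd(m, m) == 0.0
        assert hausdorff(m, m) == 0.0
        assert hd95(m, m) == 0.0

    @given(g=grids, h=grids)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dice_voe_consistency_and_bounds(self, g, h):
        if g.shape != h.shape:
            return
        pm, gt = BinaryMask(g), BinaryMask(h)
        d, v = dice(pm, gt), voe(pm, gt)
        assert 0.0 <= d <= 100.0 and 0.0 <= v <= 100.0
        if pm.volume or gt.volume:
            j = 1 - v / 100
            assert d == pytest.approx(200 * j / (1 + j), abs=1e-9)


class TestOracleEquivalence:
    def test_200_random_pairs_match_brute_force(self):
        """All eight metrics agree with the enumeration oracle to 1e-9."""
        rng = np.random.default_rng(42)
        spacings = [(1.0, 1.0), (0.5, 2.0), (1.25, 0.75)]
        for i in range(200):
            sp = spacings[i % len(spacings)]
            pm, gt = random_mask_pair(rng, max_side=16 if i % 4 else 32, spacing=sp)
            expected = brute_force_metrics(pm.grid, gt.grid, sp)
            r = evaluate_pair(pm, gt)
            got = {"DSC": r.dsc, "VOE": r.voe, "RVD": r.rvd, "ASD": r.asd,
                   "HD": r.hd, "HD95": r.hd95, "REC": r.rec, "PRE": r.pre}
            for k, v in expected.items():
                if np.isnan(v):
                    assert np.isnan(got[k]) or r.degenerate_flag, k
                else:
                    assert got[k] == pytest.approx(v, abs=1e-9), f"{k} at pair {i}"

    def test_metric_identities_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            pm, gt = random_mask_pair(rng)
            if pm.volume == 0 or gt.volume == 0:
                continue
            # DSC-VOE consistency: dice = 200 J / (1 + J)
            j = 1 - voe(pm, gt) / 100
            assert dice(pm, gt) == pytest.approx(200 * j / (1 + j), abs=1e-9)
            # symmetry
            assert dice(pm, gt) == dice(gt, pm)
            assert voe(pm, gt) == voe(gt, pm)
            assert asd(pm, gt) == pytest.approx(asd(gt, pm), abs=1e-12)
            assert hausdorff(pm, gt) == pytest.approx(hausdorff(gt, pm), abs=1e-12)
            # ordering
            assert hd95(pm, gt) <= hausdorff(pm, gt) + 1e-12
            assert asd(pm, gt) <= hausdorff(pm, gt) + 1e-12
            # rvd antisymmetry in sign
            if pm.volume != gt.volume:
                assert np.sign(rvd(pm, gt)) == -np.sign(rvd(gt, pm))

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        pm, gt = random_mask_pair(rng, max_side=12)
        pad = ((4, 4), (4, 4))
        base = evaluate_pair(
            BinaryMask(np.pad(pm.grid, pad)), BinaryMask(np.pad(gt.grid, pad)))
        shifted = evaluate_pair(
            BinaryMask(np.pad(pm.grid, ((6, 2), (1, 7)))),
            BinaryMask(np.pad(gt.grid, ((6, 2), (1, 7)))))
        for k in ("dsc", "voe", "rvd", "asd", "hd", "hd95", "rec", "pre"):
            a, b = getattr(base, k), getattr(shifted, k)
            assert a == pytest.approx(b, abs=1e-9), k
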