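import numpy as np
import pytest

from mammoseg.fuzzy_enhancement import FuzzyPlane
from mammoseg.image_io import BinaryMask, GrayImage
from mammoseg.metrics import (
    ConfusionCounts,
    boundary_pixels,
    confusion_from_masks,
    confusion_stats,
    dice,
    edgel_match_f,
    evaluate_masks,
    fuzzy_entropy,
    index_of_fuzziness,
    iou,
    local_refinement_error,
    mean_local_refinement_error,
    mse_psnr,
    nsd_enl,
    overlap_accept,
    roc_auc,
    target_background_contrast,
)


def img(arr, max_level=255):
    return GrayImage(np.asarray(arr, dtype=np.int64), max_level=max_level)


def mask(arr):
    return BinaryMask(np.asarray(arr, dtype=bool))


class TestMsePsnr:
    def test_identical_images(self):
        a = img([[1, 2], [3, 4]])
        assert mse_psnr(a, a) == (0.0, float("inf"))

    def test_unit_mse_closed_form(self):
        a = img(np.zeros((4, 4)))
        b = img(np.ones((4, 4)))
        mse, psnr = mse_psnr(a, b)
        assert mse == 1.0
        assert psnr == pytest.approx(20 * np.log10(255), abs=1e-9)

    def test_maximal_error_gives_zero_db(self):
        a = img(np.zeros((3, 3)))
        b = img(np.full((3, 3), 255))
        mse, psnr = mse_psnr(a, b)
        assert mse == 255.0**2
        assert psnr == pytest.approx(0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_psnr(img(np.zeros((2, 2))), img(np.zeros((2, 3))))


class TestNsdEnl:
    def test_constant_region(self):
        nsd, enl = nsd_enl(img(np.full((4, 4), 9)), mask(np.ones((4, 4))))
        assert nsd == 0.0 and enl == float("inf")

    def test_hand_computed_population_std(self):
        im = img([[0, 0], [2, 2]])
        nsd, enl = nsd_enl(im, mask(np.ones((2, 2))))
        assert nsd == 1.0 and enl == 1.0

    def test_intensity_scaling(self):
        r = np.random.default_rng(0)
        px = r.integers(1, 50, (6, 6))
        m = mask(np.ones((6, 6)))
        nsd1, enl1 = nsd_enl(img(px), m)
        nsd3, enl3 = nsd_enl(img(px * 3), m)
        assert nsd3 == pytest.approx(3 * nsd1)
        assert enl3 == pytest.approx(enl1)

    def test_default_region_is_border_strip(self):
        px = np.full((40, 40), 10)
        px[10:30, 10:30] = 200  # center must not influence the default strip
        nsd, enl = nsd_enl(img(px))
        assert nsd == 0.0 and enl == float("inf")

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            nsd_enl(img(np.zeros((2, 2))), mask(np.zeros((2, 2))))


class TestFuzzinessMeasures:
    @pytest.mark.parametrize(
        "values,iof,ent",
        [
            (np.array([[0.0, 1.0, 0.0, 1.0]]), 0.0, 0.0),  # crisp
            (np.full((2, 2), 0.5), 1.0, 1.0),              # maximally fuzzy
            (np.full((1, 4), 0.25), 0.5, None),            # direct sum for the index
            (np.array([[0.5, 0.0]]), None, 0.5),           # (ln2 + 0) / (2 ln2)
        ],
    )
    def test_known_values(self, values, iof, ent):
        plane = FuzzyPlane(values)
        if iof is not None:
            assert index_of_fuzziness(plane) == pytest.approx(iof)
        if ent is not None:
            assert fuzzy_entropy(plane) == pytest.approx(ent)

    def test_both_vanish_iff_crisp(self):
        r = np.random.default_rng(3)
        p = r.uniform(0.01, 0.99, (5, 5))
        plane = FuzzyPlane(p)
        assert index_of_fuzziness(plane) > 0
        assert fuzzy_entropy(plane) > 0


class TestTargetBackgroundContrast:
    def test_identical_distributions_give_zero(self):
        px = np.tile(np.array([10, 200]), (4, 2))
        t = np.zeros((4, 4), dtype=bool)
        t[:, :2] = True  # target rows see the same {10,200} mix as background
        ts, te = target_background_contrast(img(px), mask(t))
        assert ts == pytest.approx(0.0, abs=1e-9)
        assert te == pytest.approx(0.0, abs=1e-9)

    def test_constant_classes_hit_the_sentinel_cap(self):
        px = np.full((2, 4), 100)
        px[:, 2:] = 200
        t = np.zeros((2, 4), dtype=bool)
        t[:, 2:] = True
        ts, _ = target_background_contrast(img(px), mask(t))
        assert ts == 1e12  # zero-sigma classes: eps-guarded ratio is capped

    def test_contrast_doubles_with_mean_gap(self):
        r = np.random.default_rng(1)
        base = r.integers(0, 10, (6, 6))
        t = np.zeros((6, 6), dtype=bool)
        t[:3] = True
        px1 = base + 50 * t
        px2 = base + 100 * t
        s1, _ = target_background_contrast(img(px1), mask(t))
        s2, _ = target_background_contrast(img(px2), mask(t))
        assert s2 / s1 == pytest.approx(2.0, rel=0.02)


class TestRefinementError:
    def test_identical_labelings_zero_everywhere(self):
        lab = np.array([[0, 0, 1], [2, 2, 1]])
        assert mean_local_refinement_error(lab, lab) == 0.0
        for p in np.ndindex(lab.shape):
            assert local_refinement_error(lab, lab, p) == 0.0

    def test_refinement_is_one_sided(self):
        coarse = np.zeros((2, 4), dtype=int)
        fine = np.array([[0, 0, 1, 1], [0, 0, 1, 1]])
        assert mean_local_refinement_error(fine, coarse) == 0.0
        assert mean_local_refinement_error(coarse, fine) > 0.0

    def test_hand_computed_pixel_value(self):
        a = np.array([[0, 0]])  # region {p, q}
        b = np.array([[0, 1]])  # region {p}
        assert local_refinement_error(a, b, (0, 0)) == 0.5

    def test_mean_matches_per_pixel_average(self):
        r = np.random.default_rng(7)
        a = r.integers(0, 3, (4, 4))
        b = r.integers(0, 3, (4, 4))
        per_pixel = np.mean(
            [local_refinement_error(a, b, p) for p in np.ndindex(a.shape)]
        )
        assert mean_local_refinement_error(a, b) == pytest.approx(per_pixel)


class TestOverlap:
    def test_identical_accepts(self):
        m = mask(np.eye(4))
        assert overlap_accept(m, m, k=0.75)

    def test_disjoint_rejects(self):
        a = mask([[1, 0], [0, 0]])
        b = mask([[0, 0], [0, 1]])
        assert not overlap_accept(a, b)

    def test_boundary_inclusive_at_three_quarters(self):
        a = mask([[1, 1, 1, 1]])
        b = mask([[1, 1, 1, 0]])
        assert iou(a, b) == 0.75
        assert overlap_accept(a, b, k=0.75)

    def test_dice_and_iou_relation(self):
        a = mask(np.tril(np.ones((5, 5))))
        b = mask(np.triu(np.ones((5, 5))))
        j, d = iou(a, b), dice(a, b)
        assert d == pytest.approx(2 * j / (1 + j))


class TestEdgelMatch:
    def test_identical_boundaries_perfect(self):
        m = mask(np.pad(np.ones((3, 3)), 2))
        b = boundary_pixels(m)
        assert edgel_match_f(b, b) == (1.0, 1.0, 1.0)

    def test_distant_boundaries_zero(self):
        a = np.array([[0, 0]])
        b = np.array([[10, 10]])
        assert edgel_match_f(a, b, d_max=2.0) == (0.0, 0.0, 0.0)

    def test_enumerated_small_assignment(self):
        a = np.array([[0, 0], [0, 5]])
        b = np.array([[0, 1]])
        p, r, f = edgel_match_f(a, b, d_max=2.0)
        assert (p, r) == (0.5, 1.0)
        assert f == pytest.approx(2 / 3)

    def test_swap_symmetry(self):
        r = np.random.default_rng(2)
        a = r.integers(0, 15, (12, 2))
        b = r.integers(0, 15, (9, 2))
        p1, r1, f1 = edgel_match_f(a, b)
        p2, r2, f2 = edgel_match_f(b, a)
        assert (p1, r1) == (r2, p2)
        assert f1 == pytest.approx(f2)

    def test_empty_boundary_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            assert edgel_match_f(np.empty((0, 2)), np.array([[0, 0]])) == (0.0, 0.0, 0.0)

    def test_matching_is_min_cost_among_max_cardinality(self):
        # two a-edgels compete for one near b-edgel; the closer pair must win
        a = np.array([[0, 0], [0, 2]])
        b = np.array([[0, 0]])
        p, r, f = edgel_match_f(a, b, d_max=2.0)
        assert r == 1.0 and p == 0.5


class TestConfusion:
    def test_direct_ratios(self):
        s = confusion_stats(ConfusionCounts(tp=9, fp=1, tn=89, fn=1))
        assert s["sensitivity"] == pytest.approx(0.9)
        assert s["specificity"] == pytest.approx(89 / 90)
        assert s["ppv"] == pytest.approx(0.9)
        assert s["npv"] == pytest.approx(89 / 90)
        assert s["accuracy"] == pytest.approx(0.98)

    def test_perfect_classifier(self):
        s = confusion_stats(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert all(v == 1.0 for v in s.values())

    def test_undefined_sensitivity_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            s = confusion_stats(ConfusionCounts(tp=0, fp=2, tn=3, fn=0))
        assert np.isnan(s["sensitivity"])

    def test_counts_from_masks(self):
        pred = mask([[1, 1], [0, 0]])
        truth = mask([[1, 0], [0, 1]])
        c = confusion_from_masks(pred, truth)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_pair_counting(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 40))
        scores = r.integers(0, 10, n).astype(float)  # integer scores force ties
        labels = r.integers(0, 2, n).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))


class TestEvaluateMasks:
    def test_full_report_on_identical_masks(self):
        m = mask(np.pad(np.ones((4, 4)), 3))
        rep = evaluate_masks(m, m)
        assert rep.iou == 1.0 and rep.dice == 1.0 and rep.overlap_accepted
        assert rep.f_measure == 1.0
        assert rep.refinement_error_pred_vs_truth == 0.0

    def test_report_fields_within_ranges(self):
        r = np.random.default_rng(8)
        pred = mask(r.integers(0, 2, (16, 16)))
        truth = mask(r.integers(0, 2, (16, 16)))
        rep = evaluate_masks(pred, truth)
        for name in ("iou", "dice", "sensitivity", "specificity", "ppv", "npv",
                     "accuracy", "boundary_precision", "boundary_recall", "f_measure",
                     "refinement_error_pred_vs_truth", "refinement_error_truth_vs_pred"):
            v = getattr(rep, name)
            assert 0.0 <= v <= 1.0, name
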