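"""Metric oracles: confusion-derived scores against brute-force per-pixel
tallies, Hausdorff distance against an all-pairs max-min double loop, and the
boundary-extraction rule on hand-enumerable rasters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octseg.metrics import (
    boundary_points,
    confusion_counts,
    evaluate_pair,
    hausdorff_distance,
    summary_metrics,
)


def brute_force_counts(pred, truth, k):
    tp = np.zeros(k, int)
    fp = np.zeros(k, int)
    fn = np.zeros(k, int)
    tn = np.zeros(k, int)
    for l in range(k):
        for p, t in zip(pred.ravel(), truth.ravel()):
            if t == l and p == l:
                tp[l] += 1
            elif t != l and p == l:
                fp[l] += 1
            elif t == l and p != l:
                fn[l] += 1
            else:
                tn[l] += 1
    return tp, fp, fn, tn


def brute_force_hausdorff(a, b):
    def one_way(s, t):
        return max(min(np.hypot(*(p - q)) for q in t) for p in s)
    return one_way(a, b), one_way(b, a)


def test_counts_hand_example():
    truth = np.array([[0, 0], [1, 1]])
    pred = np.array([[0, 1], [1, 1]])
    c = confusion_counts(pred, truth, 2)
    assert (c.tp[1], c.fp[1], c.fn[1], c.tn[1]) == (2, 1, 0, 1)
    assert (c.tp + c.fp + c.fn + c.tn == 4).all()
    assert (c.tp + c.fn).sum() == 4


def test_counts_swap_symmetry():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 3, size=(6, 6))
    b = rng.integers(0, 3, size=(6, 6))
    c1 = confusion_counts(a, b, 3)
    c2 = confusion_counts(b, a, 3)
    np.testing.assert_array_equal(c1.fp, c2.fn)
    np.testing.assert_array_equal(c1.fn, c2.fp)
    np.testing.assert_array_equal(c1.tp, c2.tp)


def test_perfect_prediction_scores():
    truth = np.tile(np.arange(3), (4, 1))
    acc, prec, rec, dsc, undef = summary_metrics(confusion_counts(truth, truth, 3))
    assert acc == 1.0
    np.testing.assert_allclose(prec, 1.0)
    np.testing.assert_allclose(rec, 1.0)
    np.testing.assert_allclose(dsc, 1.0)
    assert not undef.any()


def test_direct_substitution_example():
    # TP=2, FP=1, FN=1 -> precision = recall = DSC = 2/3
    from octseg.metrics import ConfusionCounts
    c = ConfusionCounts(tp=np.array([2]), fp=np.array([1]),
                        fn=np.array([1]), tn=np.array([6]))
    _, prec, rec, dsc, _ = summary_metrics(c)
    assert prec[0] == pytest.approx(2 / 3)
    assert rec[0] == pytest.approx(2 / 3)
    assert dsc[0] == pytest.approx(2 / 3)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 4), st.integers(2, 16),
       st.integers(2, 16))
def test_scores_match_brute_force_tally(seed, k, h, w):
    rng = np.random.default_rng(seed)
    pred = rng.integers(0, k, size=(h, w))
    truth = rng.integers(0, k, size=(h, w))
    c = confusion_counts(pred, truth, k)
    tp, fp, fn, tn = brute_force_counts(pred, truth, k)
    np.testing.assert_array_equal(c.tp, tp)
    np.testing.assert_array_equal(c.fp, fp)
    np.testing.assert_array_equal(c.fn, fn)
    np.testing.assert_array_equal(c.tn, tn)
    acc, prec, rec, dsc, _ = summary_metrics(c)
    assert acc == (pred == truth).mean()
    for l in range(k):
        if not np.isnan(prec[l]) and not np.isnan(rec[l]) \
                and prec[l] + rec[l] > 0:
            harmonic = 2 * prec[l] * rec[l] / (prec[l] + rec[l])
            assert dsc[l] == pytest.approx(harmonic)


def test_undefined_scores_flagged_not_zero():
    truth = np.zeros((3, 3), int)
    pred = np.zeros((3, 3), int)
    _, prec, rec, _, undef = summary_metrics(confusion_counts(pred, truth, 2))
    assert np.isnan(prec[1]) and np.isnan(rec[1])
    assert undef[1] and not undef[0]


def test_boundary_full_raster_is_frame():
    labels = np.ones((5, 7), int)
    pts = {tuple(p) for p in boundary_points(labels, 1)}
    frame = {(r, c) for r in range(5) for c in range(7)
             if r in (0, 4) or c in (0, 6)}
    assert pts == frame


def test_boundary_block_perimeter():
    labels = np.zeros((7, 7), int)
    labels[2:5, 2:5] = 1
    pts = {tuple(p) for p in boundary_points(labels, 1)}
    expected = {(r, c) for r in range(2, 5) for c in range(2, 5)
                if not (r == 3 and c == 3)}
    assert pts == expected  # the 8 perimeter pixels of the 3x3 block


def test_boundary_one_pixel_wide_layer():
    labels = np.zeros((5, 5), int)
    labels[2] = 1
    pts = {tuple(p) for p in boundary_points(labels, 1)}
    assert pts == {(2, c) for c in range(5)}


def test_boundary_absent_class_raises():
    with pytest.raises(ValueError, match="absent"):
        boundary_points(np.zeros((3, 3), int), 5)


def test_hausdorff_identical_sets():
    a = np.array([[0, 0], [1, 2], [3, 3]])
    assert hausdorff_distance(a, a) == (0.0, 0.0, 0.0)


def test_hausdorff_3_4_5():
    a = np.array([[0, 0]])
    b = np.array([[3, 4]])
    assert hausdorff_distance(a, b) == (5.0, 5.0, 5.0)
    # physical scaling
    assert hausdorff_distance(a, b, pixel_pitch=2.0)[2] == 10.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000), st.integers(1, 50), st.integers(1, 50))
def test_hausdorff_matches_double_loop(seed, na, nb):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 30, size=(na, 2)).astype(float)
    b = rng.integers(0, 30, size=(nb, 2)).astype(float)
    h_ab, h_ba, h = hausdorff_distance(a, b)
    e_ab, e_ba = brute_force_hausdorff(a, b)
    assert h_ab == pytest.approx(e_ab, abs=1e-12)
    assert h_ba == pytest.approx(e_ba, abs=1e-12)
    assert h == max(h_ab, h_ba)
    # symmetry of the two-way form
    assert hausdorff_distance(b, a)[2] == pytest.approx(h, abs=1e-12)


def test_hausdorff_monotone_in_target_set():
    rng = np.random.default_rng(4)
    a = rng.integers(0, 20, size=(10, 2)).astype(float)
    b = rng.integers(0, 20, size=(10, 2)).astype(float)
    h_ab = hausdorff_distance(a, b)[0]
    b_plus = np.vstack([b, rng.integers(0, 20, size=(1, 2))])
    assert hausdorff_distance(a, b_plus)[0] <= h_ab


def test_hausdorff_empty_set_raises():
    with pytest.raises(ValueError, match="empty"):
        hausdorff_distance(np.empty((0, 2)), np.array([[1, 1]]))


def test_evaluate_pair_identical_maps():
    rng = np.random.default_rng(8)
    truth = np.repeat(np.arange(4), 16).reshape(8, 8)
    rep = evaluate_pair(truth, truth, 4)
    assert rep.accuracy == 100.0
    np.testing.assert_allclose(rep.precision, 100.0)
    np.testing.assert_allclose(rep.dsc, 100.0)
    assert rep.mean_hausdorff == 0.0
    assert len(rep.class_names) == 4
    df = rep.to_dataframe()
    assert len(df) == 5  # K per-class rows + overall
    del rng


def test_dilation_degrades_one_class_only():
    """Dilating one class lowers its DSC while other classes' recall is
    unchanged wherever they were not overwritten."""
    from scipy.ndimage import binary_dilation
    truth = np.zeros((32, 32), int)
    truth[8:16] = 1
    truth[16:24] = 2
    pred = truth.copy()
    grown = binary_dilation(truth == 1, iterations=2)
    pred[grown] = 1
    rep_base = evaluate_pair(truth, truth, 3)
    rep = evaluate_pair(pred, truth, 3)
    assert rep.dsc[1] < rep_base.dsc[1]
    # recall of the dilated class is unharmed (only others lose pixels)
    assert rep.recall[1] == pytest.approx(100.0)
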