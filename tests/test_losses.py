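"""Loss and metric oracles: hand-computed values, limits, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acaunet.grad import Tensor
from acaunet.losses import (
    combined_loss,
    confusion_counts,
    cross_entropy,
    dice_coefficient,
    overlapping_error,
)
from conftest import mask_counts, numgrad

P4 = np.array([0.9, 0.1, 0.8, 0.2], np.float32)
T4 = np.array([1.0, 0.0, 1.0, 0.0], np.float32)


# --------------------------------------------------------------- cross-entropy

def test_cross_entropy_hand_values():
    # single pixel, maximum uncertainty
    np.testing.assert_allclose(
        float(cross_entropy(np.array([0.5]), np.array([1.0])).data),
        np.log(2.0), rtol=1e-6,
    )
    # four pixels, mean of -ln .9, -ln .9, -ln .8, -ln .8
    want = np.mean([-np.log(0.9), -np.log(0.9), -np.log(0.8), -np.log(0.8)])
    np.testing.assert_allclose(float(cross_entropy(P4, T4).data), want, rtol=1e-5)
    assert abs(float(cross_entropy(P4, T4).data) - 0.16425) < 1e-4


def test_cross_entropy_perfect_prediction_is_tiny():
    t = np.array([1.0, 0.0, 1.0], np.float32)
    assert float(cross_entropy(t, t).data) < 1e-5


def test_cross_entropy_finite_at_saturated_predictions():
    val = float(cross_entropy(np.array([0.0, 1.0]), np.array([1.0, 0.0])).data)
    assert np.isfinite(val) and val > 10  # clipped, large but finite


def test_cross_entropy_rejects_non_binary_truth():
    with pytest.raises(ValueError, match="binary"):
        cross_entropy(np.array([0.5]), np.array([0.4]))


# ------------------------------------------------------------------------ dice

def test_dice_hand_values():
    t = np.array([1.0, 1.0, 0.0, 0.0], np.float32)
    np.testing.assert_allclose(float(dice_coefficient(t, t).data), 1.0)
    p = np.array([1.0, 1.0, 0.0, 0.0], np.float32)
    q = np.array([1.0, 0.0, 0.0, 0.0], np.float32)
    np.testing.assert_allclose(float(dice_coefficient(p, q).data), 2.0 / 3.0,
                               rtol=1e-6)


def test_dice_smoothing_rescues_empty_masks():
    z = np.zeros(6, np.float32)
    np.testing.assert_allclose(float(dice_coefficient(z, z, smooth=1.0).data), 1.0)


def test_dice_is_per_image_then_averaged(rng):
    p = rng.random((3, 1, 4, 4)).astype(np.float32)
    t = (rng.random((3, 1, 4, 4)) > 0.6).astype(np.float32)
    per_image = [float(dice_coefficient(p[i], t[i], smooth=1.0).data) for i in range(3)]
    np.testing.assert_allclose(float(dice_coefficient(p, t, smooth=1.0).data),
                               np.mean(per_image), rtol=1e-6)


# --------------------------------------------------------------- combined loss

def test_combined_loss_hand_value():
    # alpha=.5, S=1: 0.5*CE + 0.5*(1 - (2*1.7+1)/(2.0+2+1)) = 0.142125
    val = float(combined_loss(P4, T4, alpha=0.5, smooth=1.0).data)
    np.testing.assert_allclose(val, 0.142125, atol=5e-5)


def test_combined_loss_limits_match_components(rng):
    for _ in range(100):
        p = rng.random(8).astype(np.float32)
        t = (rng.random(8) > 0.5).astype(np.float32)
        np.testing.assert_allclose(
            float(combined_loss(p, t, alpha=1.0).data),
            float(cross_entropy(p, t).data), rtol=1e-6,
        )
        np.testing.assert_allclose(
            float(combined_loss(p, t, alpha=0.0, smooth=1.0).data),
            1.0 - float(dice_coefficient(p, t, smooth=1.0).data), rtol=1e-6,
        )


@settings(max_examples=30, derandomize=True, deadline=None)
@given(alpha=st.floats(0.0, 1.0), seed=st.integers(0, 10_000))
def test_combined_loss_is_convex_combination(alpha, seed):
    r = np.random.default_rng(seed)
    p = r.random(12).astype(np.float32)
    t = (r.random(12) > 0.5).astype(np.float32)
    ce = float(cross_entropy(p, t).data)
    inv_dice = 1.0 - float(dice_coefficient(p, t, smooth=1.0).data)
    val = float(combined_loss(p, t, alpha=alpha, smooth=1.0).data)
    lo, hi = min(ce, inv_dice), max(ce, inv_dice)
    assert lo - 1e-5 <= val <= hi + 1e-5


def test_combined_loss_gradient_matches_finite_differences(rng):
    p = rng.uniform(0.1, 0.9, size=8).astype(np.float32)
    t = (rng.random(8) > 0.5).astype(np.float32)
    pt = Tensor(p.copy(), requires_grad=True)
    combined_loss(pt, t, alpha=0.5, smooth=1.0).backward()
    num = numgrad(lambda: float(combined_loss(p, t, alpha=0.5, smooth=1.0).data),
                  p, eps=1e-3)
    err = np.abs(pt.grad - num).max() / np.abs(num).max()
    assert err < 1e-3


def test_combined_loss_rejects_bad_alpha():
    with pytest.raises(ValueError, match="alpha"):
        combined_loss(P4, T4, alpha=1.5)


# ----------------------------------------------------------------- overlap err

def test_overlap_error_enumerated_confusion_oracle():
    """4x4 masks with TP=9, FP=1, FN=2 -> E = 1 - 9/12 = 0.25."""
    truth = np.zeros((4, 4), np.uint8)
    truth[0:3, 0:4] = 1
    truth[2, 3] = 0  # 11 truth pixels
    pred = np.zeros((4, 4), np.uint8)
    pred[0:3, 0:3] = 1  # 9 overlapping
    pred[3, 3] = 1  # 1 false positive
    tp, fp, fn = mask_counts(pred, truth)
    assert (tp, fp, fn) == (9, 1, 2)
    assert confusion_counts(pred, truth) == (9, 1, 2)
    np.testing.assert_allclose(overlapping_error(pred, truth), 0.25)


def test_overlap_error_extremes():
    a = np.array([[1, 1], [0, 0]], np.uint8)
    b = np.array([[0, 0], [1, 1]], np.uint8)
    assert overlapping_error(a, a) == 0.0
    assert overlapping_error(a, b) == 1.0  # disjoint, non-empty
    z = np.zeros((2, 2), np.uint8)
    assert overlapping_error(z, z) == 0.0  # empty-vs-empty convention


def test_overlap_error_is_symmetric(rng):
    a = (rng.random((6, 6)) > 0.5).astype(np.uint8)
    b = (rng.random((6, 6)) > 0.5).astype(np.uint8)
    assert overlapping_error(a, b) == overlapping_error(b, a)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_flipping_a_correct_pixel_never_decreases_error(seed):
    r = np.random.default_rng(seed)
    truth = (r.random((5, 5)) > 0.6).astype(np.uint8)
    pred = truth.copy()
    flips = r.integers(0, 5, size=(3, 2))
    e_prev = overlapping_error(pred, truth)
    for y, x in flips:
        if pred[y, x] == truth[y, x]:
            pred[y, x] = 1 - pred[y, x]
            e_now = overlapping_error(pred, truth)
            assert e_now >= e_prev - 1e-12
            e_prev = e_now


def test_dice_and_overlap_error_identity(rng):
    """On binary masks, DC = 2(1-E)/(2-E); both are functions of TP/FP/FN."""
    for _ in range(20):
        a = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        b = (rng.random((8, 8)) > 0.4).astype(np.uint8)
        e = overlapping_error(a, b)
        dc = float(dice_coefficient(a.astype(np.float32), b.astype(np.float32)).data)
        np.testing.assert_allclose(dc, 2.0 * (1.0 - e) / (2.0 - e), rtol=1e-5)


def test_masks_must_share_a_grid():
    with pytest.raises(ValueError, match="differ"):
        overlapping_error(np.zeros((2, 2)), np.zeros((3, 3)))
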