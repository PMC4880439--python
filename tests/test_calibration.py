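import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snvconsensus.calibration import (
    fit_confidence_curve,
    moving_average,
    normalized_accuracy,
    optimize_threshold,
    predict_binary,
    transform_score,
)
from snvconsensus.core_io import HIGHER_IS_DELETERIOUS, LOWER_IS_DELETERIOUS


def exhaustive_threshold(scores, labels, polarity):
    """Independent oracle: scan every candidate threshold directly."""
    scores = list(map(float, scores))
    uniq = sorted(set(scores))
    mids = [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]
    cands = [uniq[0] - 1.0] + mids + [uniq[-1] + 1.0]
    n_d = sum(1 for l in labels if l == "D")
    n_n = len(labels) - n_d
    best = None
    for t in cands:
        tp = sum(1 for s, l in zip(scores, labels)
                 if l == "D" and (s >= t if polarity == HIGHER_IS_DELETERIOUS
                                  else s <= t))
        tn = sum(1 for s, l in zip(scores, labels)
                 if l == "N" and not (s >= t if polarity == HIGHER_IS_DELETERIOUS
                                      else s <= t))
        nacc = (tp / n_d + tn / n_n) / 2
        # tie-break toward higher sensitivity: lower threshold when higher
        # scores mean deleterious, higher threshold otherwise
        better = best is None or nacc > best[1] or (
            nacc == best[1] and (
                t < best[0] if polarity == HIGHER_IS_DELETERIOUS else t > best[0]))
        if better:
            best = (t, nacc)
    return best


class TestNormalizedAccuracy:
    def test_perfect_classifier(self):
        assert normalized_accuracy(5, 0, 5, 0) == 1.0

    def test_constant_predictor_on_balanced_set(self):
        assert normalized_accuracy(7, 7, 0, 0) == 0.5

    def test_direct_formula(self):
        assert normalized_accuracy(3, 1, 2, 0) == pytest.approx((1.0 + 2 / 3) / 2)

    def test_absent_class_is_error(self):
        with pytest.raises(ValueError):
            normalized_accuracy(3, 0, 0, 2)  # no neutral examples


class TestOptimizeThreshold:
    def test_separable_case(self):
        thr, nacc = optimize_threshold([0.8, 0.9, 0.1, 0.2], ["D", "D", "N", "N"])
        assert thr == 0.5 and nacc == 1.0

    def test_tie_breaks_toward_sensitivity(self):
        thr, nacc = optimize_threshold([0.4, 0.6, 0.9, 0.1, 0.5, 0.7],
                                       ["D", "D", "D", "N", "N", "N"])
        assert nacc == pytest.approx(2 / 3)
        assert thr == pytest.approx(0.25)

    def test_lower_is_deleterious_mirrors(self):
        thr, nacc = optimize_threshold([0.1, 0.2, 0.8, 0.9], ["D", "D", "N", "N"],
                                       LOWER_IS_DELETERIOUS)
        assert nacc == 1.0
        assert predict_binary(0.1, thr, LOWER_IS_DELETERIOUS) == "D"
        assert predict_binary(0.9, thr, LOWER_IS_DELETERIOUS) == "N"

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            optimize_threshold([0.1, 0.9], ["D", "D"])

    def test_matches_exhaustive_search(self):
        rng = random.Random(0)
        for _ in range(300):
            n = rng.randrange(4, 21)
            scores = [round(rng.uniform(0, 1), 2) for _ in range(n)]
            labels = ["D"] * (n // 2) + ["N"] * (n - n // 2)
            rng.shuffle(labels)
            pol = rng.choice([HIGHER_IS_DELETERIOUS, LOWER_IS_DELETERIOUS])
            expected = exhaustive_threshold(scores, labels, pol)
            got = optimize_threshold(scores, labels, pol)
            assert got[1] == pytest.approx(expected[1], abs=1e-12)
            assert got[0] == pytest.approx(expected[0], abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=30),
           st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=30))
    def test_accuracy_at_least_constant_predictor(self, d_scores, n_scores):
        scores = d_scores + n_scores
        labels = ["D"] * len(d_scores) + ["N"] * len(n_scores)
        _, nacc = optimize_threshold(scores, labels)
        assert nacc >= 0.5

    def test_parameter_recovery_from_gaussian_classes(self):
        """Well-separated Gaussians: threshold ~ analytic optimum 0.5 and
        training balanced accuracy ~ Phi(2)."""
        rng = np.random.default_rng(12345)
        d = rng.normal(0.7, 0.1, size=2000)
        n = rng.normal(0.3, 0.1, size=2000)
        scores = np.concatenate([d, n])
        labels = ["D"] * 2000 + ["N"] * 2000
        thr, nacc = optimize_threshold(scores, labels)
        assert 0.45 <= thr <= 0.55
        from scipy.stats import norm
        assert nacc == pytest.approx(norm.cdf(2), abs=0.02)


class TestMovingAverage:
    def test_constant_signal_invariant(self):
        v = np.full(9, 0.4)
        assert np.allclose(moving_average(v, 11), v)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.integers(1, 15))
    def test_range_preserved(self, values, window):
        v = np.array(values)
        sm = moving_average(v, window)
        assert sm.min() >= v.min() - 1e-12
        assert sm.max() <= v.max() + 1e-12


class TestConfidenceCurve:
    def test_66_bins_of_two_at_n_132(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 1, 132)
        labels = ["D" if s > 0.5 else "N" for s in scores]
        curve = fit_confidence_curve(scores, labels, 0.5)
        assert curve.n_bins == 66
        assert len(curve.bin_centers) == 66

    def test_small_n_reduces_bin_count(self):
        scores = np.linspace(0, 1, 10)
        labels = ["N"] * 5 + ["D"] * 5
        curve = fit_confidence_curve(scores, labels, 0.5, n_bins=66)
        assert curve.n_bins == 5  # floor(10 / 2)

    def test_hand_computed_moving_averages(self):
        """n=20, 5 bins of 4, window 3: smoothed values by hand."""
        scores = np.arange(20, dtype=float)
        labels = list("NNND" "NNDD" "NDDD" "DDDD" "DDDD")
        curve = fit_confidence_curve(scores, labels, 10.0, n_bins=5, window=3)
        assert curve.bin_centers == pytest.approx([1.5, 5.5, 9.5, 13.5, 17.5])
        assert curve.smoothed_frac_deleterious == pytest.approx(
            [0.25, 0.5, 0.75, (0.75 + 1 + 1) / 3, 1.0])

    def test_separated_classes_give_unit_fraction_at_the_top(self):
        scores = np.linspace(0, 1, 40)
        labels = ["N"] * 20 + ["D"] * 20
        curve = fit_confidence_curve(scores, labels, 0.5, n_bins=10, window=3)
        assert curve.smoothed_frac_deleterious[-1] == 1.0
        assert curve.smoothed_frac_deleterious[0] == 0.0

    def test_smoothing_preserves_bin_fraction_range(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 1, 200)
        labels = ["D" if rng.uniform() < s else "N" for s in scores]
        curve = fit_confidence_curve(scores, labels, 0.5)
        assert all(0 <= f <= 1 for f in curve.smoothed_frac_deleterious)

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            fit_confidence_curve([0.1, 0.9, 0.5], ["N", "D", "D"], 0.5)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            fit_confidence_curve([0.1, 0.2, 0.8, 0.9], ["D"] * 4, 0.5)


class TestTransformScore:
    @pytest.fixture()
    def curve(self):
        scores = np.linspace(0, 1, 40)
        labels = ["N"] * 20 + ["D"] * 20
        return fit_confidence_curve(scores, labels, 0.5, n_bins=10, window=3)

    def test_query_beyond_training_range_clamps(self, curve):
        pred_hi, conf_hi = transform_score(curve, 5.0, HIGHER_IS_DELETERIOUS)
        pred_top, conf_top = transform_score(curve, curve.bin_centers[-1],
                                             HIGHER_IS_DELETERIOUS)
        assert pred_hi == "D" and conf_hi == conf_top

    def test_confidence_is_scaled_side_accuracy(self):
        # build a curve whose smoothed fraction is exactly 0.75 at a center
        from snvconsensus.calibration import CalibrationCurve
        curve = CalibrationCurve(tool="t", category="c", bin_edges=[0, 1],
                                 bin_centers=[0.25, 0.75],
                                 smoothed_frac_deleterious=[0.25, 0.75],
                                 threshold=0.5, n_bins=2, window=1)
        assert transform_score(curve, 0.75, HIGHER_IS_DELETERIOUS) == ("D", 75)
        # neutral side uses the complement
        assert transform_score(curve, 0.25, HIGHER_IS_DELETERIOUS) == ("N", 75)

    def test_confidence_caps_at_99(self, curve):
        _, conf = transform_score(curve, 1.0, HIGHER_IS_DELETERIOUS)
        assert conf == 99

    def test_calibration_holds_on_held_out_data(self):
        """Per-confidence-decile empirical accuracy tracks stated confidence."""
        rng = np.random.default_rng(2024)

        def draw(n):
            d = rng.normal(0.6, 0.15, n)
            nn = rng.normal(0.4, 0.15, n)
            return (np.concatenate([d, nn]), ["D"] * n + ["N"] * n)

        s_tr, y_tr = draw(2500)
        s_te, y_te = draw(2500)
        thr, _ = optimize_threshold(s_tr, y_tr)
        curve = fit_confidence_curve(s_tr, y_tr, thr)
        out = [transform_score(curve, s, HIGHER_IS_DELETERIOUS) for s in s_te]
        confs = np.array([c for _, c in out])
        correct = np.array([p == t for (p, _), t in zip(out, y_te)])
        for decile in range(10):
            m = (confs >= 10 * decile) & (confs < 10 * (decile + 1))
            if m.sum() >= 50:
                assert abs(confs[m].mean() / 100 - correct[m].mean()) <= 0.10
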