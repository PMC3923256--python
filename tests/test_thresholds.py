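"""Operating-point statistics, ROC sweep, AUC and t_ROC selection."""

import math
import warnings

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import simcal as sc
from simcal.thresholds import _candidate_thresholds, point_from_counts

# Confusion matrices implied by published sensitivity/specificity values on a
# 49-similar / 51-non-similar training split, with the statistics they entail.
RECONSTRUCTED_ROWS = [
    # (tp, tn, fp, fn, sens, spec, precision, accuracy, f, youden, mcc)
    (49, 45, 6, 0, 1.000, 0.882, 0.891, 0.940, 0.942, 0.882, 0.8866),  # Daylight-like
    (48, 48, 3, 1, 0.980, 0.941, 0.941, 0.960, 0.960, 0.921, 0.9208),  # BCI-like
    (48, 45, 6, 1, 0.980, 0.882, 0.889, 0.930, 0.932, 0.862, 0.8645),  # ECFC4-like
    (46, 45, 6, 3, 0.939, 0.882, 0.885, 0.910, 0.911, 0.821, 0.8216),  # MDL-like
]


class TestConfusionAt:
    @pytest.mark.parametrize("tp,tn,fp,fn,sens,spec,prec,acc,f,youden,mcc", RECONSTRUCTED_ROWS)
    def test_published_operating_points_from_counts(
        self, tp, tn, fp, fn, sens, spec, prec, acc, f, youden, mcc
    ):
        op = point_from_counts(tp, tn, fp, fn)
        assert round(op.sensitivity, 3) == sens
        assert round(op.specificity, 3) == spec
        assert round(op.precision, 3) == prec
        assert round(op.accuracy, 3) == acc
        assert round(op.f_index, 3) == f
        assert round(op.youden, 3) == youden
        assert round(op.mcc, 4) == mcc

    def test_bci_like_mcc_exact_rational_value(self):
        # (48*48 - 3*1) / sqrt(51*49*51*49) = 2301/2499 exactly
        op = point_from_counts(48, 48, 3, 1)
        assert op.mcc == pytest.approx(2301 / 2499, abs=1e-15)

    def test_threshold_is_inclusive(self):
        op = sc.confusion_at([0.3, 0.5, 0.7], [False, True, True], t=0.5)
        assert (op.tp, op.tn, op.fp, op.fn) == (2, 1, 0, 0)

    def test_degenerate_threshold_zero(self):
        op = sc.confusion_at([0.1, 0.6], [True, False], t=0.0)
        assert op.sensitivity == 1.0 and op.specificity == 0.0

    def test_undefined_ratios_are_nan_not_zero(self):
        # nothing predicted similar: precision undefined
        op = sc.confusion_at([0.1, 0.2], [True, False], t=0.9)
        assert math.isnan(op.precision)
        assert math.isnan(op.mcc)
        assert op.accuracy == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sc.confusion_at([], [], 0.5)

    def test_metric_identities_on_random_points(self, rng):
        s = rng.random(80)
        y = rng.random(80) < 0.5
        for t in rng.random(10):
            op = sc.confusion_at(s, y, t)
            n = op.tp + op.tn + op.fp + op.fn
            assert op.accuracy == pytest.approx((op.tp + op.tn) / n)
            assert op.youden == pytest.approx(op.sensitivity + op.specificity - 1)
            if not math.isnan(op.precision) and op.precision + op.sensitivity > 0:
                harm = 2 * op.precision * op.sensitivity / (op.precision + op.sensitivity)
                assert op.f_index == pytest.approx(harm)


class TestRocCurve:
    def test_perfect_separation_passes_through_top_left(self):
        s = [0.1, 0.2, 0.8, 0.9]
        y = [False, False, True, True]
        curve = sc.roc_curve(s, y)
        assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in curve)
        assert sc.auc(curve) == 1.0

    def test_sweep_cardinality(self, rng):
        s = rng.choice(np.round(np.linspace(0.05, 0.95, 12), 3), 40)
        y = rng.random(40) < 0.5
        curve = sc.roc_curve(s, y)
        assert len(curve) <= len(np.unique(s)) + 1 + 2  # midpoints + sentinels

    def test_identical_similarities_collapse_to_corners(self):
        curve = sc.roc_curve([0.4] * 6, [True, False] * 3)
        pts = {(round(1 - p.specificity, 9), round(p.sensitivity, 9)) for p in curve}
        assert pts == {(0.0, 0.0), (1.0, 1.0)}
        assert sc.auc(curve) == pytest.approx(0.5)

    def test_monotone_sensitivity_along_curve(self, rng):
        s = rng.random(100)
        y = rng.random(100) < 0.4
        curve = sc.roc_curve(s, y)
        sens = [p.sensitivity for p in curve]
        assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:]))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            sc.roc_curve([0.1, 0.9], [True, True])


class TestAuc:
    def test_null_similarity_auc_near_half(self):
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(300):
            s = rng.random(100)
            y = rng.random(100) < 0.5
            if y.all() or (~y).all():
                continue
            aucs.append(sc.auc(sc.roc_curve(s, y)))
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_matches_sklearn_with_ties(self, rng):
        for _ in range(25):
            s = np.round(rng.random(60), 2)  # rounding forces ties
            y = rng.random(60) < 0.5
            if y.all() or (~y).all():
                continue
            assert sc.auc(sc.roc_curve(s, y)) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.random(80)
        y = rng.random(80) < 0.5
        base = sc.auc(sc.roc_curve(s, y))
        for transform in (np.sqrt, lambda v: v**3, lambda v: 1 / (1 + np.exp(-5 * v))):
            assert sc.auc(sc.roc_curve(transform(s), y)) == pytest.approx(base, abs=1e-12)


class TestSelectTRoc:
    def test_perfect_separation_gives_unit_youden_between_classes(self):
        s = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        y = [False, False, False, True, True, True]
        op = sc.select_t_roc(s, y)
        assert op.youden == 1.0
        assert 0.3 < op.threshold < 0.7

    def test_troc_consistent_with_tlr_at_balanced_prevalence(self):
        # panels simulated from the published calibration regime: the selected
        # threshold stays near the 0.505 probability-0.5 crossing
        hits = total = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(1, 201):
                cfg = sc.PanelSimConfig(seed=seed, beta0_true=-12.754, beta1_true=2.524)
                s = sc.simulate_similarities(cfg)
                labels = sc.simulate_votes(s, cfg) > 0.5
                if labels.all() or (~labels).all():
                    continue
                total += 1
                op = sc.select_t_roc(s, labels)
                hits += abs(op.threshold - 0.505) <= 0.08
        assert hits / total >= 0.90

    def test_label_flip_symmetry(self, rng):
        s = rng.random(60)
        y = rng.random(60) < 0.5
        cands = _candidate_thresholds(s)
        best = max(sc.confusion_at(s, y, t).youden for t in cands)
        flipped = ~y

        def inverted_youden(t):
            pred = s < t  # inverted classifier
            tp = int((pred & flipped).sum())
            fn = int((~pred & flipped).sum())
            tn = int((~pred & ~flipped).sum())
            fp = int((pred & ~flipped).sum())
            return tp / (tp + fn) + tn / (tn + fp) - 1

        assert max(inverted_youden(t) for t in cands) == pytest.approx(best, abs=1e-12)

    def test_unreachable_floors_relaxed_with_warning(self, rng):
        s = rng.random(40)
        y = rng.random(40) < 0.5
        with pytest.warns(UserWarning, match="floors relaxed"):
            op = sc.select_t_roc(s, y, min_sens=0.999, min_spec=0.999)
        cands = _candidate_thresholds(s)
        assert op.youden == pytest.approx(max(sc.confusion_at(s, y, t).youden for t in cands))
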