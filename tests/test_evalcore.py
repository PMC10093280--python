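"""Metric formulas, AUC, threshold curves and selector, paired tests."""

from fractions import Fraction

import numpy as np
import pytest

from hsitissue import (
    AnnotationMask,
    ContingencyCounts,
    ProbabilityMap,
    auc_score,
    compute_metrics,
    confusion_counts,
    mean_over_patients,
    optimal_raw_threshold,
    paired_comparison,
    sens_spec_curves,
)
from hsitissue.containers import InvalidInputError
from hsitissue.evalcore import (
    EmptyEvaluationError,
    MetricSet,
    ThresholdCurve,
    key_wavelength_importance,
    top_wavelengths,
)


def _mask(labels):
    return AnnotationMask(np.asarray(labels, dtype=np.uint8))


class TestConfusionCounts:
    def test_perfect_prediction(self):
        mask = _mask([[1, 1, 2], [2, 1, 0]])
        pred = (mask.labels == 2).astype(int)
        c = confusion_counts(pred, mask)
        assert (c.fp, c.fn) == (0, 0)
        assert (c.tp, c.tn) == (2, 3)

    def test_inverted_prediction(self):
        mask = _mask([[1, 1, 2], [2, 1, 0]])
        pred = (mask.labels == 1).astype(int)
        c = confusion_counts(pred, mask)
        assert (c.tp, c.tn) == (0, 0)

    def test_hand_counted_toy_with_margin(self):
        mask = _mask([[1, 1, 1], [1, 2, 2], [2, 2, 3]])
        c = confusion_counts(np.ones((3, 3), dtype=int), mask)
        assert (c.tp, c.fp, c.tn, c.fn) == (4, 4, 0, 0)

    def test_no_labeled_pixels_rejected(self):
        with pytest.raises(EmptyEvaluationError):
            confusion_counts(np.zeros((2, 2)), _mask([[0, 0], [3, 3]]))


def _oracle_metrics(tp, tn, fp, fn):
    """Independent rational-arithmetic metric oracle."""
    out = {}
    out["accuracy"] = Fraction(tp + tn, tp + tn + fp + fn)
    out["sensitivity"] = Fraction(tp, tp + fn) if tp + fn else None
    out["specificity"] = Fraction(tn, tn + fp) if tn + fp else None
    out["f1_cancerous"] = (Fraction(2 * tp, 2 * tp + fp + fn)
                           if 2 * tp + fp + fn else None)
    out["f1_nonmalignant"] = (Fraction(2 * tn, 2 * tn + fn + fp)
                              if 2 * tn + fn + fp else None)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["mcc"] = ((tp * tn - fp * fn) / np.sqrt(float(denom))
                  if denom else 0.0)
    return out


class TestMetrics:
    def test_perfect_counts(self):
        m = compute_metrics(ContingencyCounts(tp=50, tn=50, fp=0, fn=0))
        for name in ("accuracy", "sensitivity", "specificity",
                     "f1_cancerous", "f1_nonmalignant", "mcc"):
            assert getattr(m, name) == 1.0

    def test_hand_arithmetic_example(self):
        m = compute_metrics(ContingencyCounts(tp=30, fn=10, tn=40, fp=20))
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.f1_cancerous == pytest.approx(2 / 3)
        assert m.mcc == pytest.approx(0.40824829, abs=1e-8)

    def test_against_rational_oracle_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 200, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(ContingencyCounts(int(tp), int(tn),
                                                  int(fp), int(fn)))
            oracle = _oracle_metrics(int(tp), int(tn), int(fp), int(fn))
            for name, expected in oracle.items():
                got = getattr(m, name)
                if expected is None:
                    assert np.isnan(got)
                elif isinstance(expected, Fraction):
                    assert got == pytest.approx(float(expected), abs=1e-12)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_mcc_symmetric_under_class_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            tp, tn, fp, fn = (int(x) for x in rng.integers(1, 100, 4))
            a = compute_metrics(ContingencyCounts(tp, tn, fp, fn)).mcc
            b = compute_metrics(ContingencyCounts(tn, tp, fn, fp)).mcc
            assert a == pytest.approx(b, abs=1e-12)

    def test_random_predictions_have_near_zero_mcc(self):
        rng = np.random.default_rng(8)
        mccs = []
        for _ in range(20):
            truth = rng.random(10_000) < 0.1
            pred = rng.random(10_000) < 0.5
            tp = int((pred & truth).sum())
            tn = int((~pred & ~truth).sum())
            fp = int((pred & ~truth).sum())
            fn = int((~pred & truth).sum())
            mccs.append(compute_metrics(
                ContingencyCounts(tp, tn, fp, fn)).mcc)
        assert abs(np.mean(mccs)) < 0.1


class TestAUC:
    def test_separated_probabilities(self):
        mask = _mask([[2, 2, 1, 1]])
        pm = ProbabilityMap(np.array([[0.9, 0.8, 0.2, 0.1]]),
                            mask.class_pixels())
        assert auc_score(pm, mask) == 1.0

    def test_six_pixel_toy(self):
        mask = _mask([[2, 2, 2, 1, 1, 1]])
        pm = ProbabilityMap(np.array([[0.9, 0.8, 0.4, 0.7, 0.3, 0.1]]),
                            mask.class_pixels())
        assert auc_score(pm, mask) == pytest.approx(8 / 9)

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(3)
        labels = rng.permutation([1] * 500 + [2] * 500).reshape(20, 50)
        pm = ProbabilityMap(rng.random((20, 50)), labels > 0)
        assert abs(auc_score(pm, _mask(labels)) - 0.5) < 0.06

    def test_concordant_pair_oracle_on_all_small_sets(self):
        """Midrank AUC equals the concordant-pair count on <=8-pixel sets."""
        rng = np.random.default_rng(9)
        for n in range(2, 9):
            for _ in range(60):
                labels = rng.integers(1, 3, size=n)
                if len(set(labels)) < 2:
                    continue
                probs = np.round(rng.random(n), 2)  # induce ties
                pos, neg = probs[labels == 2], probs[labels == 1]
                pairs = sum(1.0 if p > q else 0.5 if p == q else 0.0
                            for p in pos for q in neg)
                expected = pairs / (len(pos) * len(neg))
                pm = ProbabilityMap(probs[None], np.ones((1, n), bool))
                assert auc_score(pm, _mask(labels[None])) == pytest.approx(
                    expected, abs=1e-12)

    def test_single_class_undefined(self):
        mask = _mask([[1, 1]])
        pm = ProbabilityMap(np.array([[0.2, 0.4]]), mask.class_pixels())
        assert np.isnan(auc_score(pm, mask))


class TestThresholdCurves:
    def _random_patient(self, rng, h=12, w=15):
        labels = rng.integers(1, 3, size=(h, w))
        pm = ProbabilityMap(np.clip(rng.random((h, w)), 1e-6, 1 - 1e-6),
                            labels > 0)
        return pm, _mask(labels)

    def test_extremes(self):
        rng = np.random.default_rng(1)
        pm, mask = self._random_patient(rng)
        curve = sens_spec_curves([pm], [mask],
                                 thresholds=np.array([0.0, 0.5, 1.0]))
        assert curve.sens_at[0] == 1.0  # every p > 0
        assert curve.spec_at[-1] == 1.0  # no p > 1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        maps, masks = zip(*(self._random_patient(rng) for _ in range(5)))
        curve = sens_spec_curves(list(maps), list(masks))
        assert (np.diff(curve.sens_at) <= 1e-12).all()
        assert (np.diff(curve.spec_at) >= -1e-12).all()

    def test_empty_patient_list_rejected(self):
        with pytest.raises(EmptyEvaluationError):
            sens_spec_curves([], [])


class TestOptimalThreshold:
    def test_identical_curves_return_smallest_grid_point(self):
        grid = np.linspace(0, 1, 11)
        curve = ThresholdCurve(grid, np.full(11, 0.7), np.full(11, 0.7))
        t, s, c = optimal_raw_threshold(curve)
        assert t == 0.0

    def test_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            grid = np.linspace(0, 1, 101)
            sens = np.sort(rng.random(101))[::-1]
            spec = np.sort(rng.random(101))
            curve = ThresholdCurve(grid, sens, spec)
            t, _, _ = optimal_raw_threshold(curve)
            best, best_t = None, None
            for i in range(101):  # independent scan, first minimum
                gap = abs(sens[i] - spec[i])
                if best is None or gap < best:
                    best, best_t = gap, grid[i]
            assert t == best_t

    def test_balanced_uniform_scores_cross_at_half(self):
        rng = np.random.default_rng(6)
        n = 20_000
        labels = np.concatenate([np.full(n // 2, 2), np.full(n // 2, 1)])
        probs = np.concatenate([rng.uniform(0.5, 1.0, n // 2),
                                rng.uniform(0.0, 0.5, n // 2)])
        pm = ProbabilityMap(probs[None], np.ones((1, n), bool))
        curve = sens_spec_curves([pm], [_mask(labels[None])])
        t, s, c = optimal_raw_threshold(curve)
        assert t == pytest.approx(0.5, abs=0.02)
        assert s > 0.98 and c > 0.98


class TestAveraging:
    def test_identical_sets_mean_and_zero_sd(self):
        m = MetricSet(accuracy=0.9, sensitivity=0.8, specificity=0.7,
                      f1_nonmalignant=0.95, f1_cancerous=0.6, auc=0.97,
                      mcc=0.5)
        mean, sd = mean_over_patients([m, m, m])
        assert mean.sensitivity == pytest.approx(0.8)
        assert sd.sensitivity == pytest.approx(0.0, abs=1e-12)

    def test_two_patient_sample_sd(self):
        mean, sd = mean_over_patients([MetricSet(sensitivity=0.8),
                                       MetricSet(sensitivity=0.6)])
        assert mean.sensitivity == pytest.approx(0.7)
        assert sd.sensitivity == pytest.approx(np.std([0.8, 0.6], ddof=1))

    def test_undefined_entries_skipped(self):
        sets = [MetricSet(sensitivity=0.9), MetricSet(sensitivity=np.nan),
                MetricSet(sensitivity=0.7)]
        mean, _ = mean_over_patients(sets)
        assert mean.sensitivity == pytest.approx(0.8)

    def test_all_undefined_propagates(self):
        mean, sd = mean_over_patients([MetricSet(), MetricSet()])
        assert np.isnan(mean.sensitivity) and np.isnan(sd.sensitivity)


class TestPairedComparison:
    def test_identical_vectors(self):
        v = np.linspace(0.5, 0.9, 10)
        c = paired_comparison(v, v)
        assert c.t_statistic == 0.0 and c.p_value == 1.0

    def test_constant_shift_is_degenerate(self):
        v = np.linspace(0.5, 0.9, 10)
        c = paired_comparison(v, v + 0.05)
        assert c.degenerate and c.p_value == 0.0

    def test_nan_pairs_dropped(self):
        b = np.array([0.5, np.nan, 0.7, 0.6])
        p = np.array([0.6, 0.9, 0.9, 0.5])
        assert paired_comparison(b, p).n_patients == 3

    def test_null_pvalues_uniform(self):
        """Under the null the p-value distribution is uniform (KS check)."""
        from scipy.stats import kstest
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(1000):
            b = rng.normal(size=10)
            p = rng.normal(size=10)
            pvals.append(paired_comparison(b, p).p_value)
        assert kstest(pvals, "uniform").pvalue > 1e-3

    def test_matches_scipy_directly(self):
        from scipy.stats import ttest_rel
        rng = np.random.default_rng(2)
        b, p = rng.random(12), rng.random(12)
        c = paired_comparison(b, p)
        ref = ttest_rel(p, b)
        assert c.t_statistic == pytest.approx(ref.statistic)
        assert c.p_value == pytest.approx(ref.pvalue)


class TestKeyWavelengths:
    def test_zeroed_model_has_zero_importance(self, training_samples):
        from hsitissue import ArchitectureSpec, build_model
        from hsitissue.models import RS
        train, _ = training_samples
        model = build_model(ArchitectureSpec(name=RS, width_scale=0.05))
        for p in model.params():
            p.value[...] = 0.0
        imp = key_wavelength_importance(model, train.subset(np.arange(120)))
        assert imp.shape == (92,)
        np.testing.assert_array_equal(imp, 0.0)

    def test_contrast_window_dominates_importance(self):
        """Models trained on 900-1000 nm contrast rank those bands first."""
        from hsitissue import (ArchitectureSpec, PhantomConfig, SampleSet,
                               TrainingConfig, build_model,
                               exclude_noisy_channels, extract_samples,
                               generate_cohort, scale_cube, train_classifier)
        from hsitissue.models import RS
        from hsitissue.preprocess import compute_class_weights

        hits = 0
        for seed in range(3):
            cfg = PhantomConfig(n_patients=2, height=24, width=32,
                                class_contrast=3.0,
                                contrast_window_weights=(0.0, 1.0),
                                seed=70 + seed)
            cohort = generate_cohort(cfg)
            cubes = [scale_cube(exclude_noisy_channels(p.cube),
                                "standardization") for p in cohort]
            ss = SampleSet.concatenate([
                extract_samples(c, p.mask, p.patient_id)
                for c, p in zip(cubes, cohort)])
            idx = np.random.default_rng(seed).permutation(len(ss))[:300]
            train = ss.subset(idx)
            model = build_model(ArchitectureSpec(name=RS, width_scale=0.15,
                                                 init_seed=seed))
            model, _ = train_classifier(
                model, train, train.subset(np.arange(0)),
                TrainingConfig(epochs=8, learning_rate=1e-3, seed=seed),
                compute_class_weights(train))
            imp = key_wavelength_importance(model, train.subset(np.arange(150)))
            wl = 540.0 + 5.0 * np.arange(92)
            top = top_wavelengths(imp, wl, k=5)
            hits += sum(1 for nm, _ in top if 850.0 <= nm <= 1000.0)
        assert hits >= 8  # majority of the 15 top slots across seeds
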