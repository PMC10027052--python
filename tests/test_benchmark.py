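import numpy as np
import pandas as pd
import pytest

from timecellbench.benchmark import (ALGORITHMS, best_concordance_threshold,
                                     concordance_classify, concordance_sweep,
                                     confusion, metrics, otsu_threshold,
                                     parameter_sensitivity,
                                     prediction_correlations,
                                     roc_and_threshold, score_correlations)


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert (c.fp, c.fn) == (0, 0) and (c.tp, c.tn) == (2, 1)

    def test_inverted_prediction(self):
        c = confusion([0, 1], [1, 0])
        assert (c.tp, c.tn) == (0, 0)

    def test_enumerated_case(self):
        c = confusion([1, 0, 1, 0], [1, 1, 0, 0])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetrics:
    def test_worked_example(self):
        m = metrics(confusion([1] * 4 + [0], [1, 1, 1, 0, 1]))
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)

    def test_perfect_classifier(self):
        m = metrics(confusion([1, 0, 1], [1, 0, 1]))
        assert m.recall == m.precision == m.f1 == m.accuracy == 1.0

    def test_no_true_positives(self):
        m = metrics(confusion([0, 0, 0], [1, 1, 0]))
        assert m.recall == 0 and m.f1 == 0 and m.degenerate

    def test_agrees_with_definitional_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(2, 60))
            pred = rng.random(n) < 0.5
            truth = rng.random(n) < 0.5
            c = confusion(pred, truth)
            assert c.total == n
            m = metrics(c)
            if c.tp + c.fn and c.tp + c.fp and c.tp:
                assert m.recall == pytest.approx(c.tp / (c.tp + c.fn))
                assert m.precision == pytest.approx(c.tp / (c.tp + c.fp))
                assert min(m.precision, m.recall) <= m.f1 + 1e-12
                assert m.f1 <= (m.precision + m.recall) / 2 + 1e-12


def between_class_variance(scores, t):
    left = scores[scores <= t]
    right = scores[scores > t]
    if left.size == 0 or right.size == 0:
        return 0.0
    w0 = left.size / scores.size
    return w0 * (1 - w0) * (left.mean() - right.mean()) ** 2


def brute_force_otsu(scores, n_bins=256):
    """Oracle: exhaustive search over the same candidate bin edges,
    evaluating the between-class variance directly on the data."""
    scores = np.asarray(scores, dtype=float)
    lo, hi = scores.min(), scores.max()
    candidates = [lo + (k + 1) / n_bins * (hi - lo) for k in range(n_bins - 1)]
    return max(candidates, key=lambda t: between_class_variance(scores, t))


class TestOtsu:
    def test_separable_binary_scores(self):
        scores = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        t = otsu_threshold(scores)
        assert 0 < t < 1
        assert np.array_equal(scores > t, scores.astype(bool))

    def test_constant_scores_sentinel(self):
        assert otsu_threshold(np.full(10, 3.3)) == np.inf

    def test_matches_exhaustive_search(self):
        """The histogram threshold must achieve (up to histogram
        quantisation) the same between-class variance as an exhaustive
        data-level search over the same candidate thresholds."""
        rng = np.random.default_rng(1)
        for _ in range(30):
            scores = np.concatenate([rng.normal(0, 1, 40),
                                     rng.normal(4, 1, 25)])
            t = otsu_threshold(scores)
            oracle = brute_force_otsu(scores)
            v_t = between_class_variance(scores, t)
            v_star = between_class_variance(scores, oracle)
            assert v_t >= 0.995 * v_star

    def test_matches_skimage_reference(self):
        skimage = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.normal(0, 1, 200), rng.normal(5, 1, 100)])
        t = otsu_threshold(scores)
        ref = skimage.threshold_otsu(scores, nbins=256)
        span = scores.max() - scores.min()
        assert abs(t - ref) <= span / 256 + 1e-9


class TestCorrelations:
    def test_self_and_negation(self):
        rng = np.random.default_rng(3)
        x = rng.random(50) < 0.5
        df = pd.DataFrame({a: x for a in ALGORITHMS})
        df[ALGORITHMS[1]] = ~x
        corr = prediction_correlations(df)
        assert corr.iloc[0, 0] == pytest.approx(1.0)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_independent_booleans_uncorrelated(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({a: rng.random(10_000) < 0.5 for a in ALGORITHMS})
        corr = prediction_correlations(df).to_numpy()
        off_diag = corr[~np.eye(len(ALGORITHMS), dtype=bool)]
        assert np.abs(off_diag).max() < 0.05

    def test_zero_variance_column_is_nan(self):
        df = pd.DataFrame({"tiMean_score": np.ones(10),
                           "tiBase_score": np.arange(10.0),
                           "r2bBase_score": np.arange(10.0) ** 2,
                           "peqBase_score": np.arange(10.0) ** 0.5})
        corr = score_correlations(df)
        assert np.isnan(corr.loc["tiMean_score", "tiBase_score"])


class TestRoc:
    def test_perfectly_separating_scores(self):
        r = roc_and_threshold([0, 0.1, 0.2, 0.8, 0.9, 1.0],
                              [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(1.0)
        assert 0.2 < r.best_threshold <= 0.8

    def test_uninformative_scores_auc_half(self):
        rng = np.random.default_rng(5)
        scores = rng.random(4000)
        truth = rng.random(4000) < 0.5
        r = roc_and_threshold(scores, truth)
        assert r.auc == pytest.approx(0.5, abs=0.05)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(6)
        scores = rng.random(300)
        truth = scores + rng.normal(0, 0.3, 300) > 0.5
        a = roc_and_threshold(scores, truth).auc
        b = roc_and_threshold(-scores, truth).auc
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="classes"):
            roc_and_threshold([0.1, 0.2], [1, 1])


class TestConcordance:
    def test_union_and_intersection(self):
        rng = np.random.default_rng(7)
        preds = rng.random((10, 40)) < 0.4
        assert np.array_equal(concordance_classify(preds, 1), preds.any(axis=0))
        assert np.array_equal(concordance_classify(preds, 10), preds.all(axis=0))

    def test_counting_threshold(self):
        preds = np.zeros((10, 1), dtype=bool)
        preds[:4, 0] = True
        assert concordance_classify(preds, 4)[0]
        assert not concordance_classify(preds, 5)[0]

    def test_best_threshold_not_worse_than_worst_algorithm(self):
        rng = np.random.default_rng(8)
        truth = rng.random(400) < 0.5
        # algorithms of varying quality
        preds = np.array([np.where(rng.random(400) < err, ~truth, truth)
                          for err in np.linspace(0.05, 0.45, 10)])
        sweep = concordance_sweep(preds, truth)
        worst_single = min(
            metrics(confusion(p, truth)).f1 for p in preds)
        assert sweep["f1"].max() >= worst_single
        assert 1 <= best_concordance_threshold(preds, truth) <= 10


class TestParameterSensitivity:
    @staticmethod
    def _frame(f1_fn, levels=(10.0, 40.0, 70.0), seeds=6):
        rows = [{"algorithm": "a1", "level": lv, "f1": f1_fn(lv, s)}
                for lv in levels for s in range(seeds)]
        return pd.DataFrame(rows)

    def test_constant_f1_not_significant(self):
        rng = np.random.default_rng(9)
        df = self._frame(lambda lv, s: 0.9 + rng.normal(0, 0.01))
        r = parameter_sensitivity(df, "noise")[0]
        assert abs(r.slope) < 0.005 and not r.significant

    def test_linear_f1_recovers_slope(self):
        df = self._frame(lambda lv, s: 1 - 0.005 * lv + 1e-6 * s)
        r = parameter_sensitivity(df, "noise")[0]
        assert r.slope == pytest.approx(-0.005, abs=1e-4)
        assert r.p_value < 1e-6 and r.significant

    def test_two_levels_exact_slope(self):
        df = self._frame(lambda lv, s: 1 - 0.01 * lv, levels=(10.0, 20.0))
        r = parameter_sensitivity(df, "noise")[0]
        assert r.slope == pytest.approx(-0.01)

    def test_degenerate_design_errors(self):
        df = pd.DataFrame([{"algorithm": "a", "level": 1.0, "f1": 0.5}])
        with pytest.raises(ValueError):
            parameter_sensitivity(df)
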