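"""Figures of merit, exact binomial intervals, ROC/AUC (with a pairwise
concordance oracle), and the cross-validated AUC interval."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from serscv.metrics import (
    _auc_mann_whitney,
    average_roc,
    binomial_ci,
    cv_auc_confidence_interval,
    fom_from_confusion,
    roc_auc_per_repetition,
    summarize_foms,
)


def pairwise_auc(scores, labels):
    """Brute-force concordance AUC: fraction of (positive, negative) pairs
    ordered correctly, ties half credit."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestFOM:
    def test_printed_median_counts(self):
        # 62 of 72 positives correctly predicted
        foms = fom_from_confusion({"tp": 62, "fn": 10, "tn": 50, "fp": 22})
        assert foms["sensitivity"] == pytest.approx(62 / 72)

    def test_all_ones_symmetry(self):
        foms = fom_from_confusion({"tp": 1, "fp": 1, "tn": 1, "fn": 1})
        assert all(v == pytest.approx(0.5) for v in foms.values())

    def test_perfect_classifier(self):
        foms = fom_from_confusion({"tp": 5, "fp": 0, "tn": 7, "fn": 0})
        assert all(v == pytest.approx(1.0) for v in foms.values())

    def test_zero_denominator_is_nan_not_zero(self):
        foms = fom_from_confusion({"tp": 0, "fp": 0, "tn": 3, "fn": 2})
        assert np.isnan(foms["ppv"])
        assert foms["npv"] == pytest.approx(0.6)

    def test_accuracy_identity(self, signal_results):
        """accuracy = (sens*n_pos + spec*n_neg) / n, exactly, per repetition."""
        for rep in signal_results.repetitions:
            cm = rep.confusion
            f = fom_from_confusion(cm)
            n_pos = cm["tp"] + cm["fn"]
            n_neg = cm["tn"] + cm["fp"]
            expected = (f["sensitivity"] * n_pos + f["specificity"] * n_neg) / (
                n_pos + n_neg
            )
            assert f["accuracy"] == pytest.approx(expected)


class TestBinomialCI:
    def test_zero_successes_closed_form(self):
        lo, hi = binomial_ci(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-4)
        assert round(hi, 4) == 0.3085

    def test_all_successes_boundary(self):
        lo, hi = binomial_ci(10, 10)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-6)

    @given(st.integers(1, 200), st.data())
    @settings(max_examples=50, deadline=None)
    def test_interval_contains_point_estimate(self, n, data):
        x = data.draw(st.integers(0, n))
        lo, hi = binomial_ci(x, n)
        assert lo - 1e-12 <= x / n <= hi + 1e-12

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 4)


class TestROCAUC:
    def test_perfect_ordering(self, signal_results):
        curve = roc_auc_per_repetition(
            signal_results.repetitions[0], "H0T"
        )
        assert 0.0 <= curve.auc <= 1.0
        assert curve.fpr[0] == 0.0 and curve.fpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    @given(
        st.integers(2, 12),
        st.integers(2, 12),
        st.integers(0, 10_000),
        st.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_trapezoid_equals_pairwise_concordance(self, n1, n0, seed, tie):
        """Rank-based AUC = brute-force pairwise oracle on random instances,
        with and without ties."""
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n1 + n0)
        if tie:  # coarse rounding forces ties
            scores = np.round(scores, 1)
        labels = np.array([1] * n1 + [0] * n0)
        assert _auc_mann_whitney(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels)
        )

    def test_label_flip_symmetry(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.uniform(size=30) < 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = _auc_mann_whitney(scores, labels)
        b = _auc_mann_whitney(scores, 1 - labels)
        assert a == pytest.approx(1.0 - b)

    def test_average_roc_endpoints(self, signal_results):
        grid, mean_tpr = average_roc(signal_results.roc_curves())
        assert grid.size == 201
        assert mean_tpr[0] >= 0.0 and mean_tpr[-1] == pytest.approx(1.0)


class TestSummarizeFOMs:
    def test_one_value_per_repetition(self, signal_results):
        fom = signal_results.fom_summary()
        assert len(fom.values) == signal_results.config.n_rep
        for m in ("sensitivity", "specificity", "accuracy", "ppv", "npv",
                  "auc"):
            row = fom.table.loc[m]
            assert 0.0 <= row["ci_lo"] <= row["ci_hi"] <= 1.0

    def test_ci_nondegenerate_when_repetitions_identical(self, signal_results):
        fom = signal_results.fom_summary()
        # binomial CI has positive width even if every repetition agrees
        for m in ("sensitivity", "specificity", "accuracy"):
            row = fom.table.loc[m]
            assert row["ci_hi"] - row["ci_lo"] > 0


class TestCVAUCInterval:
    def test_perfect_folds_truncate_at_one(self):
        folds = []
        for _ in range(6):
            scores = np.array([0.9, 0.8, 0.2, 0.1])
            labels = np.array([1, 1, 0, 0])
            folds.append((scores, labels))
        mean_auc, lo, hi = cv_auc_confidence_interval(folds)
        assert mean_auc == 1.0
        assert hi == 1.0

    def test_single_class_fold_excluded_with_warning(self):
        good = (np.array([0.9, 0.1, 0.8, 0.3]), np.array([1, 0, 1, 0]))
        bad = (np.array([0.5, 0.6]), np.array([1, 1]))
        with pytest.warns(RuntimeWarning, match="single class"):
            mean_auc, lo, hi = cv_auc_confidence_interval([good, bad])
        assert 0.0 <= lo <= mean_auc <= hi <= 1.0

    def test_width_shrinks_with_n(self):
        """Quadrupling n at fixed AUC roughly halves the interval width."""
        def make_fold(n, rng):
            pos = rng.normal(1.0, 1.0, size=n)
            neg = rng.normal(0.0, 1.0, size=n)
            return (np.concatenate([pos, neg]),
                    np.array([1] * n + [0] * n))

        rng = np.random.default_rng(7)
        _, lo1, hi1 = cv_auc_confidence_interval([make_fold(100, rng)])
        rng = np.random.default_rng(7)
        _, lo4, hi4 = cv_auc_confidence_interval([make_fold(400, rng)])
        ratio = (hi1 - lo1) / (hi4 - lo4)
        assert 1.5 < ratio < 2.7  # ~2 expected, Monte-Carlo slack

    def test_agrees_with_bootstrap_single_fold(self):
        """IC-based interval vs a percentile bootstrap on one fold: the
        intervals overlap and widths agree within 30%."""
        rng = np.random.default_rng(42)
        n = 150
        pos = rng.normal(0.8, 1.0, size=n)
        neg = rng.normal(0.0, 1.0, size=n)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * n + [0] * n)
        mean_auc, lo, hi = cv_auc_confidence_interval([(scores, labels)])

        boot = []
        for _ in range(500):
            idx = rng.integers(0, len(scores), size=len(scores))
            s, l = scores[idx], labels[idx]
            if l.min() == l.max():
                continue
            boot.append(_auc_mann_whitney(s, l))
        blo, bhi = np.percentile(boot, [2.5, 97.5])
        assert max(lo, blo) < min(hi, bhi)  # intervals overlap
        w_ic, w_boot = hi - lo, bhi - blo
        assert abs(w_ic - w_boot) / w_boot < 0.30
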