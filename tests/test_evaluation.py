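"""ROC/AUC, Youden cutoff, Welch t, Kaplan-Meier and log-rank checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ferroscore as fs
from ferroscore.exceptions import ValidationError


def pairwise_auc(scores, labels):
    """Exhaustive Mann-Whitney pair count with ties worth 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def welch_oracle(a, b):
    """Textbook Welch statistic and Welch-Satterthwaite p-value."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    t = (b.mean() - a.mean()) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1)
                                     + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def logrank_oracle(times, events, groups):
    """Risk-table summation: observed minus expected events in group 1."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    names = sorted(set(groups), key=str)
    event_times = np.unique(times[events == 1])
    o_minus_e, var = 0.0, 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == names[1])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == names[1])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / var
    return chi2, stats.chi2.sf(chi2, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        roc = fs.roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.sens_at_cutoff == 1.0
        assert roc.spec_at_cutoff == 1.0

    def test_tied_scores(self):
        roc = fs.roc_auc([0.9, 0.5, 0.5, 0.2], [1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.875, abs=1e-12)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        auc = fs.roc_auc(scores, labels).auc
        flipped = fs.roc_auc(scores, 1 - labels).auc
        assert flipped == pytest.approx(1 - auc, abs=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1),
           st.integers(min_value=2, max_value=30))
    def test_matches_pairwise_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        # quantized scores force ties to exercise the 1/2 convention
        scores = np.round(rng.normal(size=n), 1)
        labels = rng.integers(0, 2, size=n)
        labels[0], labels[1] = 0, 1
        roc = fs.roc_auc(scores, labels)
        assert roc.auc == pytest.approx(pairwise_auc(scores, labels),
                                        abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        base = fs.roc_auc(scores, labels)
        warped = fs.roc_auc(np.exp(3 * scores), labels)
        assert warped.auc == pytest.approx(base.auc, abs=1e-12)
        assert warped.youden_j == pytest.approx(base.youden_j, abs=1e-12)

    def test_constant_scores(self):
        roc = fs.roc_auc([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0])
        assert roc.auc == 0.5
        assert roc.youden_j == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fs.roc_auc([0.1, 0.2], [1, 1])


class TestYouden:
    def test_null_scores_give_small_j(self):
        small = 0
        n_reps = 100
        for rep in range(n_reps):
            rng = np.random.default_rng(rep)
            scores = rng.normal(size=200)
            labels = rng.integers(0, 2, size=200)
            labels[:2] = [0, 1]
            roc = fs.roc_auc(scores, labels)
            small += roc.youden_j < 0.25
        assert small / n_reps >= 0.9

    def test_cutoff_classifies_by_geq(self):
        roc = fs.roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        cutoff, sens, spec = fs.youden_cutoff(roc)
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        predicted = scores >= cutoff
        np.testing.assert_array_equal(predicted, [True, True, False, False])


class TestCompareGroups:
    def test_identical_groups(self):
        t, p = fs.compare_groups([1.0, 1.0, 1.0, 1.0], [0, 0, 1, 1])
        assert t == 0.0 and p == 1.0

    def test_matches_welch_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 15))
            b = rng.normal(0.5, 2, size=rng.integers(3, 15))
            scores = np.concatenate([a, b])
            labels = np.array([0] * len(a) + [1] * len(b))
            t, p = fs.compare_groups(scores, labels)
            t_exp, p_exp = welch_oracle(a, b)
            assert t == pytest.approx(t_exp, abs=1e-10)
            assert p == pytest.approx(p_exp, abs=1e-10)

    def test_null_rejection_rate(self):
        rejections = 0
        n_reps = 2000
        rng = np.random.default_rng(3)
        for _ in range(n_reps):
            scores = rng.normal(size=20)
            labels = np.array([0] * 10 + [1] * 10)
            _, p = fs.compare_groups(scores, labels)
            rejections += p < 0.05
        rate = rejections / n_reps
        assert abs(rate - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / n_reps)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            fs.compare_groups([1.0, 2.0, 3.0], [0, 1, 1])


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curve = fs.km_curve([5, 10, 15], [0, 0, 0])
        assert (curve.survival == 1.0).all()

    def test_hand_product_limit(self):
        curve = fs.km_curve([1, 2, 3, 4], [1, 0, 1, 0])
        assert curve.at(1) == pytest.approx(0.75, abs=1e-10)
        assert curve.at(3) == pytest.approx(0.375, abs=1e-10)

    def test_reduces_to_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, size=25)
        curve = fs.km_curve(times, np.ones(25, dtype=int))
        for t in np.linspace(0, times.max(), 30):
            assert curve.at(t) == pytest.approx((times > t).mean(), abs=1e-10)

    def test_curve_monotone_in_unit_interval(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, size=40)
        events = rng.integers(0, 2, size=40)
        events[0] = 1
        curve = fs.km_curve(times, events)
        assert curve.survival[0] == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert ((curve.survival >= 0) & (curve.survival <= 1)).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            fs.km_curve([], [])


class TestLogrank:
    def test_mirrored_groups_give_zero(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = [0, 0, 0, 0, 1, 1, 1, 1]
        chi2, p = fs.logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_matches_risk_table_oracle(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(5, size=10).round(2)
        events = rng.integers(0, 2, size=10)
        events[:2] = 1
        groups = np.array([0] * 5 + [1] * 5)
        chi2, p = fs.logrank_test(times, events, groups)
        chi2_exp, p_exp = logrank_oracle(times, events, groups)
        assert chi2 == pytest.approx(chi2_exp, abs=1e-10)
        assert p == pytest.approx(p_exp, abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            fs.logrank_test([1, 2], [0, 0], [0, 1])


class TestFixedHorizonRoc:
    def test_perfect_ranking(self):
        roc = fs.fixed_horizon_roc([3.0, 2.0, 1.0, 0.0],
                                   [10, 20, 2000, 2000], [1, 1, 0, 0],
                                   horizon=1095)
        assert roc.auc == 1.0
        assert roc.n_excluded == 0

    def test_all_censored_before_horizon_rejected(self):
        with pytest.raises(ValidationError, match="4 excluded"):
            fs.fixed_horizon_roc([1, 2, 3, 4], [10, 20, 30, 40],
                                 [0, 0, 0, 0], horizon=1095)

    def test_exclusion_counted(self):
        roc = fs.fixed_horizon_roc([3.0, 2.0, 1.0, 0.5, 0.1],
                                   [100, 50, 2000, 1500, 900],
                                   [1, 0, 0, 0, 0], horizon=1095)
        assert roc.n_excluded == 2  # censored at 50 and 900 days
        assert roc.n_pos == 1 and roc.n_neg == 2


class TestSurvivalReport:
    def test_median_split_report(self, default_cohort):
        _, matrix, phenotypes, truth = default_cohort
        table = phenotypes.data.set_index("sample_id")
        report = fs.survival_report(truth.latent_scores.loc[table.index],
                                    table["time"].to_numpy(),
                                    table["event"].to_numpy(),
                                    horizon=1095.0)
        assert set(report.km_curves) == {"high", "low"}
        assert report.logrank_chi2 >= 0
        for curve in report.km_curves.values():
            assert curve.survival[0] == 1.0
            assert (np.diff(curve.survival) <= 1e-12).all()
        assert 0.0 <= report.horizon_roc.auc <= 1.0

    def test_quantile_rule_monotone_invariant(self):
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.normal(size=60),
                           index=[f"S{i}" for i in range(60)])
        groups = fs.split_by_score(scores, "q0.5")
        warped = fs.split_by_score(pd.Series(np.exp(scores), index=scores.index),
                                   "q0.5")
        assert (groups == warped).all()
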