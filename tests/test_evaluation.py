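"""Metric implementations against hand values, brute force and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats
from sklearn import metrics as skm

from afuq import evaluation as ev
from afuq.uncertainty import PredictionSet
from oracles import (brier_bf, confusion_bf, ece_bf, holm_bf,
                     mann_whitney_u_bf, nll_bf)


def _preds(p, y, std=None, noisy=None, ood=None, mode="none"):
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    n = p.size
    return PredictionSet(
        mean=p,
        std=np.zeros(n) if std is None else np.asarray(std, float),
        labels=y,
        noisy=np.zeros(n, bool) if noisy is None else np.asarray(noisy, bool),
        ood=np.zeros(n, bool) if ood is None else np.asarray(ood, bool),
        mode=mode,
    )


class TestClassificationMetrics:
    def test_hand_confusion_table(self):
        # TP=2 FP=1 FN=1 TN=6
        p = [0.9, 0.8, 0.2, 0.7, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        f1, ppv, sens, spec = ev.classification_metrics(_preds(p, y))
        assert ppv == pytest.approx(2 / 3)
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(6 / 7)
        assert f1 == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        f1, ppv, sens, spec = ev.classification_metrics(
            _preds([0.9, 0.9, 0.1], [1, 1, 0]))
        assert (f1, ppv, sens, spec) == (1.0, 1.0, 1.0, 1.0)

    def test_all_negative_degenerate(self):
        f1, ppv, sens, spec = ev.classification_metrics(
            _preds([0.1, 0.2, 0.3], [1, 1, 0]))
        assert f1 == 0.0 and sens == 0.0 and spec == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ev.UndefinedMetricError):
            ev.classification_metrics(_preds([0.9, 0.1], [1, 1]))

    def test_agreement_with_sklearn_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            p = rng.random(n)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            f1, ppv, sens, spec = ev.classification_metrics(_preds(p, y))
            yhat = (p > 0.5).astype(int)
            assert f1 == pytest.approx(skm.f1_score(y, yhat, zero_division=0))
            assert ppv == pytest.approx(
                skm.precision_score(y, yhat, zero_division=0))
            assert sens == pytest.approx(skm.recall_score(y, yhat))


class TestProperScores:
    @pytest.mark.parametrize("p,y,expected", [
        ([1.0, 0.0], [1, 0], 0.0),
        ([0.5, 0.5], [1, 0], 0.25),
        ([0.8, 0.4], [1, 0], 0.10),
    ])
    def test_brier_hand_values(self, p, y, expected):
        assert ev.brier(_preds(p, y)) == pytest.approx(expected)

    @pytest.mark.parametrize("p,y,expected", [
        ([0.5], [1], np.log(2)),
        ([0.9, 0.9], [1, 1], -np.log(0.9)),
    ])
    def test_nll_hand_values(self, p, y, expected):
        assert ev.nll(_preds(p, y)) == pytest.approx(expected)

    def test_nll_perfect_clamped(self):
        assert ev.nll(_preds([1.0, 0.0], [1, 0])) == pytest.approx(0.0, abs=1e-5)

    def test_brier_nll_match_bruteforce_and_sklearn(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(5, 50))
            p = rng.random(n)
            y = rng.integers(0, 2, n)
            preds = _preds(p, y)
            assert ev.brier(preds) == pytest.approx(brier_bf(p, y), abs=1e-12)
            assert ev.nll(preds) == pytest.approx(nll_bf(p, y), abs=1e-12)
            assert ev.brier(preds) == pytest.approx(
                skm.brier_score_loss(y, p), abs=1e-12)
            if len(np.unique(y)) == 2:
                assert ev.nll(preds) == pytest.approx(
                    skm.log_loss(y, np.clip(p, 1e-7, 1 - 1e-7)), abs=1e-9)


class TestEce:
    def test_perfectly_calibrated_extremes(self):
        score, _ = ev.ece(_preds([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0]))
        assert score == pytest.approx(0.0)

    def test_single_occupied_bin(self):
        score, bins = ev.ece(_preds([0.8] * 4, [1, 1, 1, 0]))
        assert score == pytest.approx(0.05)
        assert (bins["count"] > 0).sum() == 1

    def test_right_open_binning_hand_value(self):
        score, _ = ev.ece(_preds([0.95, 0.9, 0.1, 0.05], [1, 1, 0, 0]))
        assert score == pytest.approx(0.075)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(5, 80))
            p = rng.random(n)
            y = rng.integers(0, 2, n)
            n_bins = int(rng.integers(1, 15))
            score, _ = ev.ece(_preds(p, y), n_bins)
            assert score == pytest.approx(ece_bf(p, y, n_bins), abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.random(40)
        y = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        a, _ = ev.ece(_preds(p, y))
        b, _ = ev.ece(_preds(p[perm], y[perm]))
        assert a == pytest.approx(b, abs=1e-14)

    def test_bin_table_recovers_scalar(self):
        rng = np.random.default_rng(5)
        p = rng.random(60)
        y = rng.integers(0, 2, 60)
        score, bins = ev.ece(_preds(p, y))
        occupied = bins[bins["count"] > 0]
        recomputed = (occupied["count"] / 60
                      * (occupied["acc"] - occupied["conf"]).abs()).sum()
        assert score == pytest.approx(recomputed, abs=1e-12)

    def test_duplication_scales_correctly(self):
        p = np.array([0.2, 0.7, 0.9])
        y = np.array([0, 1, 1])
        a = ev.brier(_preds(p, y))
        b = ev.brier(_preds(np.tile(p, 3), np.tile(y, 3)))
        assert a == pytest.approx(b)


class TestConfidenceCountCurve:
    def test_boundary_thresholds(self):
        preds = _preds([0.9, 0.6, 0.3], [1, 1, 0])
        curve = ev.confidence_count_curve(preds, np.array([0.0, 1.0]))
        assert curve["count"].tolist() == [2, 0]

    def test_hand_count(self):
        preds = _preds([0.9, 0.6], [1, 1])
        curve = ev.confidence_count_curve(preds, np.array([0.7]))
        assert curve["count"].tolist() == [1]

    def test_counts_non_increasing(self):
        rng = np.random.default_rng(6)
        preds = _preds(rng.random(50), rng.integers(0, 2, 50))
        curve = ev.confidence_count_curve(preds)
        assert (np.diff(curve["count"]) <= 0).all()


class TestCohenKappa:
    def test_identical_vectors(self):
        assert ev.cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_hand_table(self):
        assert ev.cohen_kappa([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(0.5)

    def test_constant_agreement_undefined(self):
        with pytest.raises(ev.UndefinedMetricError):
            ev.cohen_kappa([1, 1], [1, 1])

    def test_matches_sklearn_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            a = rng.integers(0, 3, n)
            b = rng.integers(0, 3, n)
            try:
                mine = ev.cohen_kappa(a, b)
            except ev.UndefinedMetricError:
                continue
            assert mine == pytest.approx(skm.cohen_kappa_score(a, b), abs=1e-12)


class TestMannWhitney:
    def test_hand_pair_counting(self):
        assert ev.mann_whitney_u([1, 3], [2, 4]).u_statistic == 1.0

    def test_extreme_separation(self):
        assert ev.mann_whitney_u([1, 2], [5, 6]).u_statistic == 0.0

    def test_identical_multisets_half(self):
        cmp = ev.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert cmp.u_statistic == 4.5

    def test_u_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            x = rng.integers(0, 10, rng.integers(2, 10)).astype(float)
            y = rng.integers(0, 10, rng.integers(2, 10)).astype(float)
            assert ev.mann_whitney_u(x, y).u_statistic == \
                pytest.approx(mann_whitney_u_bf(x, y))

    def test_exact_p_matches_scipy_small_samples(self):
        """Exact enumeration agrees with the reference distribution for all
        tie-free samples with n1, n2 <= 8."""
        rng = np.random.default_rng(9)
        for _ in range(60):
            n1, n2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            pooled = rng.permutation(100)[:n1 + n2].astype(float)
            x, y = pooled[:n1], pooled[n1:]
            mine = ev.mann_whitney_u(x, y)
            ref = spstats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact")
            assert mine.u_statistic == pytest.approx(ref.statistic)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_matches_scipy_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            x = rng.integers(0, 5, 25).astype(float)
            y = rng.integers(1, 6, 30).astype(float)
            mine = ev.mann_whitney_u(x, y)
            ref = spstats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ev.mann_whitney_u([], [1.0])


class TestHolm:
    def test_hand_stepdown(self):
        reject = ev.holm_correct([0.002, 0.03], alpha=0.01)
        assert reject.tolist() == [True, False]

    def test_all_ones_no_rejection(self):
        assert not ev.holm_correct([1.0, 1.0, 1.0], alpha=0.05).any()

    def test_single_test_reduces_to_plain(self):
        assert ev.holm_correct([0.009], alpha=0.01).tolist() == [True]

    def test_matches_statsmodels_and_bruteforce(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(100):
            m = int(rng.integers(1, 10))
            p = np.round(rng.random(m), 3)
            alpha = float(rng.choice([0.01, 0.05]))
            mine = ev.holm_correct(p, alpha)
            ref = multipletests(p, alpha=alpha, method="holm")[0]
            np.testing.assert_array_equal(mine, ref)
            np.testing.assert_array_equal(mine, holm_bf(list(p), alpha))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_decisions_monotone_in_p(self, p_values):
        reject = ev.holm_correct(p_values, alpha=0.05)
        p = np.asarray(p_values)
        if reject.any():
            threshold = p[reject].max()
            assert reject[p < threshold].all() or (p < threshold).sum() == 0


class TestGroupComparisons:
    def test_identical_groups_not_rejected(self):
        rng = np.random.default_rng(12)
        u = rng.random(60)
        preds = _preds(np.full(60, 0.5), np.zeros(60, int).tolist(), std=u,
                       noisy=[False, True] * 30)
        preds.labels = np.array([0, 1] * 30)
        preds.std = np.concatenate([u[:30], u[:30]])
        out = ev.compare_uncertainty_groups(preds, ("clean_vs_noisy",))
        assert out[0].reject is False

    def test_large_shift_rejected(self):
        rng = np.random.default_rng(13)
        base = rng.random(50)
        std = np.concatenate([base, base + 5.0])
        preds = _preds(np.full(100, 0.5), [0, 1] * 50, std=std,
                       noisy=[False] * 50 + [True] * 50)
        out = ev.compare_uncertainty_groups(preds, ("clean_vs_noisy",),
                                            alpha=0.01)
        assert out[0].reject is True
        assert out[0].p_value < 1e-6

    def test_empty_group_skipped_with_notice(self):
        preds = _preds([0.5] * 10, [0, 1] * 5, std=np.random.rand(10))
        out = ev.compare_uncertainty_groups(preds, ("id_vs_ood",))
        assert np.isnan(out[0].p_value) and out[0].reject is None

    def test_family_correction_applied_across_groupings(self):
        rng = np.random.default_rng(14)
        n = 120
        std = rng.random(n)
        ood = np.zeros(n, bool)
        ood[:30] = True
        std[:30] += 4.0  # OOD much more uncertain
        noisy = np.zeros(n, bool)
        noisy[30:60] = True
        labels = np.where(ood, -1, rng.integers(0, 2, n))
        preds = _preds(np.full(n, 0.5), labels, std=std, noisy=noisy, ood=ood)
        out = ev.compare_uncertainty_groups(preds)
        assert len(out) == 4
        by_name = {c.name: c for c in out}
        assert by_name["id_vs_ood"].reject is True


def test_metrics_report_ranges(tiny_trained_model, small_cohort):
    from afuq.uncertainty import UncertaintyConfig, batch_uncertainty

    preds = batch_uncertainty(tiny_trained_model, small_cohort[:40],
                              UncertaintyConfig(mode="none", n_passes=1))
    report = ev.metrics_report(preds, "tiny")
    row = report.to_row()
    for key in ("F1", "PPV", "Sensitivity", "Specificity", "ECE", "Brier"):
        assert 0.0 <= row[key] <= 1.0
    assert row["NLL"] >= 0.0
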