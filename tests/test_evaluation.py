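"""ROC construction, balanced-point metrics and descriptive statistics."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from atpbind import (
    BindingAnnotation,
    balanced_point_metrics,
    positional_state_frequencies,
    roc_points,
    site_composition_table,
)
from atpbind.evaluation import evaluate_scores
from atpbind.profiles_io import CategoricalTrack

from conftest import make_window


def brute_force_roc(scores, labels):
    """Exhaustive threshold sweep: one point per distinct score + 'above all'."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = np.sum(labels == 1), np.sum(labels == 0)
    thresholds = [np.inf] + sorted(set(scores), reverse=True)
    pts = []
    for t in thresholds:
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        pts.append((fp / neg, tp / pos))
    return np.array(pts)


def mann_whitney_auc(scores, labels):
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return u / (len(pos) * len(neg))


class TestRocPoints:
    def test_perfect_inverted_and_tied(self):
        labels = np.array([1, 1, 0, 0])
        assert roc_points(np.array([0.9, 0.8, 0.2, 0.1]), labels).auc == 1.0
        assert roc_points(np.array([0.1, 0.2, 0.8, 0.9]), labels).auc == 0.0
        tied = roc_points(np.ones(4) * 0.5, labels)
        assert tied.auc == 0.5  # single diagonal segment
        assert len(tied.thresholds) == 2

    @pytest.mark.parametrize("trial", range(30))
    def test_agrees_with_exhaustive_sweep(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 13))
        # few distinct values to force ties
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        curve = roc_points(scores, labels)
        expected = brute_force_roc(scores, labels)
        got = np.column_stack([curve.fpr, curve.tpr])
        np.testing.assert_allclose(np.sort(got, axis=0), np.sort(expected, axis=0),
                                   atol=1e-12)
        assert curve.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        a = roc_points(scores, labels).auc
        for f in (lambda s: 3 * s + 2, np.tanh, lambda s: np.exp(s / 2)):
            assert roc_points(f(scores), labels).auc == pytest.approx(a, abs=1e-12)

    def test_endpoints_and_monotone(self, rng):
        scores = rng.normal(size=30)
        labels = np.array([0, 1] * 15)
        c = roc_points(scores, labels)
        assert (c.fpr[0], c.tpr[0]) == (0.0, 0.0)
        assert (c.fpr[-1], c.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_points(np.array([0.1, 0.2]), np.array([1, 1]))


class TestBalancedPoint:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        rep = evaluate_scores(scores, labels)
        assert rep.equal_error_rate == 0.0
        assert rep.sensitivity == rep.specificity == rep.accuracy == rep.precision == 1.0

    def test_hand_enumerated_interleaved_case(self):
        # pos = {0.9, 0.4}, neg = {0.6, 0.1}: the FPR = FNR point sits at a
        # threshold between 0.4 and 0.6 where TP=FN=FP=TN=1
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        labels = np.array([1, 1, 0, 0])
        rep = evaluate_scores(scores, labels)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (1, 1, 1, 1)
        assert rep.sensitivity == rep.specificity == rep.precision == rep.accuracy == 0.5
        assert rep.equal_error_rate == pytest.approx(0.5)

    def test_exchangeable_null_eer_near_half(self):
        rng = np.random.default_rng(77)
        scores = rng.normal(size=2000)
        labels = np.array([0] * 1000 + [1] * 1000)
        rep = evaluate_scores(scores, labels)
        assert abs(rep.equal_error_rate - 0.5) <= 0.05

    def test_interpolated_fpr_equals_fnr(self, rng):
        # independent recomputation of the crossing on the straddling segment
        scores = rng.normal(size=101)
        labels = rng.integers(0, 2, size=101)
        labels[:2] = [0, 1]
        curve = roc_points(scores, labels)
        rep = balanced_point_metrics(curve, scores, labels)
        fnr = 1 - curve.tpr
        j = next(i for i in range(len(fnr)) if curve.fpr[i] >= fnr[i])
        if curve.fpr[j] == fnr[j]:
            fpr_x = fnr_x = curve.fpr[j]
        else:
            d0 = curve.fpr[j - 1] - fnr[j - 1]
            d1 = curve.fpr[j] - fnr[j]
            t = -d0 / (d1 - d0)
            fpr_x = curve.fpr[j - 1] + t * (curve.fpr[j] - curve.fpr[j - 1])
            fnr_x = fnr[j - 1] + t * (fnr[j] - fnr[j - 1])
        assert abs(fpr_x - fnr_x) <= 1e-9
        assert rep.equal_error_rate == pytest.approx(fpr_x, abs=1e-12)

    def test_metric_identities_from_counts(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        rep = evaluate_scores(scores, labels)
        total = rep.tp + rep.tn + rep.fp + rep.fn
        assert total == 80
        assert rep.accuracy * total == pytest.approx(rep.tp + rep.tn)
        assert rep.sensitivity * (rep.tp + rep.fn) == pytest.approx(rep.tp)
        assert rep.specificity * (rep.tn + rep.fp) == pytest.approx(rep.tn)
        if rep.tp + rep.fp:
            assert rep.precision * (rep.tp + rep.fp) == pytest.approx(rep.tp)


class TestPositionalFrequencies:
    def test_constant_center(self):
        wins = [make_window("CHC") for _ in range(5)]
        table = positional_state_frequencies(wins, "ss3")
        assert table.frequency(0, "H") == 1.0
        assert table.frequency(-1, "C") == 1.0

    def test_rows_sum_to_one(self, rng):
        wins = [
            make_window("".join(rng.choice(list("HEC"), size=7))) for _ in range(40)
        ]
        table = positional_state_frequencies(wins, "ss3")
        np.testing.assert_allclose(table.frequencies.sum(axis=1), 1.0, atol=1e-9)

    def test_binomial_recovery_of_center_rate(self, rng):
        p, n = 0.02, 1000
        wins = [
            make_window(
                "O" + ("D" if rng.random() < p else "O") + "O", kind="disorder2"
            )
            for _ in range(n)
        ]
        table = positional_state_frequencies(wins, "disorder2")
        assert abs(table.frequency(0, "D") - p) <= 3 * np.sqrt(p * (1 - p) / n)


class TestSiteComposition:
    def test_toy_counting(self):
        track = CategoricalTrack("c1", "disorder2", "OOOD")
        ann = {"c1": BindingAnnotation("c1", frozenset({1, 2, 3, 4}))}
        df = site_composition_table([track], ann)
        assert df.loc[("disorder2", "Ordered"), "binding_pct"] == pytest.approx(75.0)
        assert df.loc[("disorder2", "Disordered"), "binding_pct"] == pytest.approx(25.0)

    def test_identical_content_gives_identical_rows(self):
        tracks = [
            CategoricalTrack("c1", "ss3", "CHE"),
            CategoricalTrack("c2", "ss3", "CHE"),
        ]
        ann = {
            "c1": BindingAnnotation("c1", frozenset({1, 2, 3})),
            "c2": BindingAnnotation("c2", frozenset()),
        }
        df = site_composition_table(tracks, ann)
        np.testing.assert_allclose(df["binding_pct"], df["nonbinding_pct"])

    def test_percentages_sum_to_100(self, rng):
        tracks = [
            CategoricalTrack("c1", "ss3", "".join(rng.choice(list("HEC"), size=50))),
            CategoricalTrack("c1", "access2", "".join(rng.choice(list("eb"), size=50))),
        ]
        ann = {"c1": BindingAnnotation("c1", frozenset(range(1, 11)))}
        df = site_composition_table(tracks, ann)
        for kind in ("ss3", "access2"):
            for col in ("binding_pct", "nonbinding_pct"):
                assert df.loc[kind][col].sum() == pytest.approx(100.0, abs=0.1)
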