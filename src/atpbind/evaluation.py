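"""ROC curves, balanced-point metrics, and descriptive site statistics.

Plain accuracy is misleading on residue data where non-binding residues
dominate, so the headline operating point here is the *balanced* ROC point:
the threshold at which the false positive rate equals the false negative
rate (the intersection of the ROC curve with the line through (0, 1) and
(1, 0)). Sensitivity, specificity, precision and accuracy are reported from
the confusion matrix at the nearest realizable threshold, together with the
interpolated equal error rate and the threshold-free AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .biprofile import ENCODER_ALPHABETS
from .profiles_io import TRACK_ALPHABETS, CategoricalTrack
from .windowing import BindingAnnotation, LabeledWindow

__all__ = [
    "ROCCurve",
    "EvaluationReport",
    "PositionalFrequencyTable",
    "roc_points",
    "balanced_point_metrics",
    "evaluate_scores",
    "positional_state_frequencies",
    "site_composition_table",
]


@dataclass
class ROCCurve:
    """Empirical ROC points (thresholds descending) and trapezoidal AUC.

    The decision rule at ``thresholds[j]`` is ``score >= thresholds[j]``;
    tied scores share one step. The first point is (FPR, TPR) = (0, 0)
    (threshold above every score) and the last is (1, 1).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds, self.tpr, self.fpr))


@dataclass
class EvaluationReport:
    """AUC plus confusion metrics at the balanced (equal-error) ROC point."""

    auc: float
    equal_error_rate: float  # interpolated FPR = FNR value
    balanced_threshold: float  # nearest realizable threshold
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "equal_error_rate": self.equal_error_rate,
            "balanced_threshold": self.balanced_threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def roc_points(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """Empirical ROC curve over the distinct score thresholds.

    AUC is the trapezoidal area, which with grouped ties equals the
    Mann-Whitney probability (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def _confusion_at(scores: np.ndarray, labels: np.ndarray, thr: float):
    pred = scores >= thr
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, tn, fn


def balanced_point_metrics(
    curve: ROCCurve, scores: np.ndarray, labels: np.ndarray
) -> EvaluationReport:
    """Metrics at the ROC point where FPR equals FNR.

    The exact equal-error rate is found by linear interpolation between the
    two adjacent empirical ROC points straddling the line TPR = 1 - FPR.
    Confusion counts come from the nearest realizable threshold (ties broken
    toward higher sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fpr, tpr = curve.fpr, curve.tpr
    fnr = 1.0 - tpr
    d = fpr - fnr  # monotone non-decreasing along the curve, from -1 to +1
    j = int(np.searchsorted(d, 0.0, side="left"))
    if j >= len(d):
        eer = float(fpr[-1])
    elif d[j] == 0.0 or j == 0:
        eer = float(fpr[j])
    else:
        d0, d1 = d[j - 1], d[j]
        t = 0.0 if d1 == d0 else -d0 / (d1 - d0)
        eer = float(fpr[j - 1] + t * (fpr[j] - fpr[j - 1]))

    # nearest realizable point: minimize |FPR - FNR|, ties toward higher TPR
    gap = np.abs(d)
    best = np.flatnonzero(gap == gap.min())
    j_real = int(best[np.argmax(tpr[best])])
    thr = float(curve.thresholds[j_real])
    if np.isinf(thr):  # sklearn's sentinel "above every score"
        thr = float(np.max(scores)) + 1.0
    tp, fp, tn, fn = _confusion_at(scores, labels, thr)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    return EvaluationReport(
        auc=curve.auc,
        equal_error_rate=eer,
        balanced_threshold=thr,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        accuracy=acc,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def evaluate_scores(scores: np.ndarray, labels: np.ndarray) -> EvaluationReport:
    """Convenience: ROC curve + balanced-point report in one call."""
    curve = roc_points(scores, labels)
    return balanced_point_metrics(curve, scores, labels)


@dataclass
class PositionalFrequencyTable:
    """State frequencies per window offset (center at offset 0)."""

    track_kind: str
    alphabet: tuple[str, ...]
    offsets: np.ndarray  # -(w-1)/2 ... +(w-1)/2
    frequencies: np.ndarray  # w x |alphabet|, rows sum to 1

    def frequency(self, offset: int, state: str) -> float:
        i = int(np.flatnonzero(self.offsets == offset)[0])
        return float(self.frequencies[i, self.alphabet.index(state)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.frequencies, index=self.offsets, columns=list(self.alphabet)
        )


def positional_state_frequencies(
    windows: list[LabeledWindow], track_kind: str
) -> PositionalFrequencyTable:
    """Frequency of each track state at each offset from the window center.

    Padding counts as its own state, so each offset's frequencies sum to 1
    over the full encoder alphabet.
    """
    if not windows:
        raise ValueError("no windows supplied")
    alphabet = ENCODER_ALPHABETS[track_kind]
    index = {a: j for j, a in enumerate(alphabet)}
    w = windows[0].width
    counts = np.zeros((w, len(alphabet)))
    from .biprofile import _window_symbols

    for win in windows:
        if win.width != w:
            raise ValueError("mixed window widths")
        for i, s in enumerate(_window_symbols(win, track_kind)):
            counts[i, index[s]] += 1
    half = (w - 1) // 2
    return PositionalFrequencyTable(
        track_kind=track_kind,
        alphabet=alphabet,
        offsets=np.arange(-half, half + 1),
        frequencies=counts / len(windows),
    )


_STATE_NAMES = {
    "disorder2": {"O": "Ordered", "D": "Disordered"},
    "ss3": {"C": "Coil (C)", "H": "Helical (H)", "E": "Strand (E)"},
    "access2": {"e": "Exposed (e)", "b": "Buried (b)"},
}


def site_composition_table(
    tracks: list[CategoricalTrack],
    annotations: dict[str, BindingAnnotation],
) -> pd.DataFrame:
    """Per-class state percentages for each track, binding vs non-binding.

    Returns a DataFrame indexed by (track kind, state name) with columns
    ``binding_pct`` and ``nonbinding_pct``; within each (class, track) the
    percentages sum to 100.
    """
    counts: dict[tuple[str, str, int], int] = {}
    totals: dict[tuple[str, int], int] = {}
    for track in tracks:
        ann = annotations.get(track.chain_id)
        binding = ann.binding_positions if ann else frozenset()
        for pos, state in enumerate(track.states, start=1):
            cls = int(pos in binding)
            counts[(track.kind, state, cls)] = counts.get((track.kind, state, cls), 0) + 1
            totals[(track.kind, cls)] = totals.get((track.kind, cls), 0) + 1
    rows = []
    for kind in ("disorder2", "ss3", "access2"):
        if (kind, 0) not in totals and (kind, 1) not in totals:
            continue
        for state in TRACK_ALPHABETS[kind]:
            name = _STATE_NAMES[kind][state]
            row = {"track": kind, "state": name}
            for cls, col in ((1, "binding_pct"), (0, "nonbinding_pct")):
                total = totals.get((kind, cls), 0)
                n = counts.get((kind, state, cls), 0)
                row[col] = 100.0 * n / total if total else float("nan")
            rows.append(row)
    return pd.DataFrame(rows).set_index(["track", "state"])
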