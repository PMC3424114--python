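"""End-to-end cross-validated protocol driver.

For each negative:positive ratio and each chain-level fold the driver

1. fits bi-profile posterior tables on *training-fold* windows only (the
   encoder sees labels, so fitting it on test chains would leak),
2. subsamples training negatives to the requested ratio,
3. grid-search-trains the RBF-SVM on the fused feature matrix,
4. scores every window of the held-out test chains (natural imbalance),

then pools the held-out scores over folds into one balanced-point
evaluation report per (feature set, ratio). A machine-readable run log
records the derived seeds and the (C, g) chosen per fold.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .biprofile import (
    BLOCK_ORDER,
    TRACK_FOR_BLOCK,
    BiProfileModel,
    build_feature_matrix,
    fit_biprofile,
)
from .classifier import TrainingConfig, grid_search_train, predict_scores
from .dataset import SamplingPlan, make_chain_folds, subsample_negatives
from .evaluation import EvaluationReport, evaluate_scores
from .synthetic import SyntheticSpec, generate_synthetic_dataset
from .windowing import LabeledWindow, extract_windows

__all__ = ["RunConfig", "ProtocolResult", "run_protocol", "fit_fold_encoders", "LeakageError"]


class LeakageError(RuntimeError):
    """Raised when encoder fitting is handed windows from test chains."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one protocol run needs.

    Exactly one of ``synthetic`` or (``chains`` + ``profiles`` + ``tracks``
    + ``annotations``) supplies the data. ``feature_sets`` is a list of
    block-name lists; one report is produced per (feature set, ratio).
    """

    synthetic: SyntheticSpec | None = None
    chains: list | None = None
    profiles: dict | None = None
    tracks: dict | None = None
    annotations: dict | None = None
    window_width: int = 17
    feature_sets: tuple[tuple[str, ...], ...] = (("LogisticPSSM", "Bipro-ss"),)
    ratios: tuple[int, ...] = (1,)
    cv_folds: int | str = 5  # integer k, or "loocv"
    training: TrainingConfig = field(default_factory=TrainingConfig)
    pseudocount: float = 1.0
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        has_synth = self.synthetic is not None
        has_real = self.chains is not None
        if has_synth == has_real:
            raise ValueError("supply exactly one of a synthetic spec or real inputs")
        if not self.ratios:
            raise ValueError("ratio list must be nonempty")
        for fs in self.feature_sets:
            bad = [b for b in fs if b not in BLOCK_ORDER]
            if bad:
                raise ValueError(f"unknown feature blocks {bad}")


@dataclass
class ProtocolResult:
    """Pooled reports plus per-residue predictions and the run log."""

    reports: dict[tuple[str, int], EvaluationReport]
    predictions: dict[tuple[str, int], list[dict]]
    run_log: dict


def fit_fold_encoders(
    train_windows: list[LabeledWindow],
    track_kinds: list[str],
    train_chain_ids: frozenset[str],
    pseudocount: float = 1.0,
) -> dict[str, BiProfileModel]:
    """Fit one bi-profile model per track kind on training windows only.

    Refuses any window whose chain is outside ``train_chain_ids`` — the
    guard that makes label leakage through the encoder impossible.
    """
    outside = sorted({w.chain_id for w in train_windows} - train_chain_ids)
    if outside:
        raise LeakageError(
            f"bi-profile fitting received windows from non-training chains: {outside}"
        )
    pos = [w for w in train_windows if w.label == 1]
    neg = [w for w in train_windows if w.label == 0]
    return {
        kind: fit_biprofile(pos, neg, kind, pseudocount=pseudocount)
        for kind in track_kinds
    }


def _windows_by_chain(cfg: RunConfig):
    if cfg.synthetic is not None:
        ds = generate_synthetic_dataset(cfg.synthetic)
        chains = ds.chains
        profiles, tracks, annotations = ds.profiles, ds.tracks, ds.annotations
    else:
        chains = cfg.chains
        profiles, tracks, annotations = cfg.profiles, cfg.tracks, cfg.annotations
    by_chain = {}
    for chain in chains:
        by_chain[chain.id] = (
            chain,
            extract_windows(
                chain,
                profiles[chain.id],
                tracks[chain.id],
                annotations.get(chain.id),
                w=cfg.window_width,
            ),
        )
    return by_chain


def run_protocol(cfg: RunConfig) -> ProtocolResult:
    """Run the full cross-validated protocol; see the module docstring."""
    by_chain = _windows_by_chain(cfg)
    chain_ids = sorted(by_chain)
    k = len(chain_ids) if cfg.cv_folds == "loocv" else int(cfg.cv_folds)

    root = np.random.SeedSequence(cfg.seed)
    fold_seed, sub_seed, train_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    )
    folds = make_chain_folds(chain_ids, k, fold_seed)

    reports: dict[tuple[str, int], EvaluationReport] = {}
    predictions: dict[tuple[str, int], list[dict]] = {}
    log: dict = {
        "seed": cfg.seed,
        "fold_seed": fold_seed,
        "subsample_seed": sub_seed,
        "train_seed": train_seed,
        "k": k,
        "folds": {cid: int(f) for cid, f in folds.assignment.items()},
        "runs": [],
    }

    for fs in cfg.feature_sets:
        fs_name = "+".join(fs)
        kinds = [TRACK_FOR_BLOCK[b] for b in fs if b in TRACK_FOR_BLOCK]
        for ratio in cfg.ratios:
            pooled_scores: list[float] = []
            pooled_labels: list[int] = []
            preds: list[dict] = []
            for fold in range(k):
                train_ids = folds.train_chains(fold)
                test_ids = folds.test_chains(fold)
                train_windows = [
                    w for cid in sorted(train_ids) for w in by_chain[cid][1]
                ]
                encoders = fit_fold_encoders(
                    train_windows, kinds, train_ids, cfg.pseudocount
                )
                plan = SamplingPlan(ratio=ratio, seed=sub_seed + fold)
                sampled = subsample_negatives(train_windows, plan)
                X_train = build_feature_matrix(sampled, list(fs), encoders)
                y_train = np.array([w.label for w in sampled])
                predictor = grid_search_train(
                    X_train, y_train, cfg.training, seed=train_seed + fold
                )
                log["runs"].append(
                    {
                        "feature_set": fs_name,
                        "ratio": ratio,
                        "fold": fold,
                        "C": predictor.C,
                        "g": predictor.g,
                        "inner_auc": predictor.inner_auc,
                        "n_train": len(sampled),
                    }
                )
                test_windows = [
                    w for cid in sorted(test_ids) for w in by_chain[cid][1]
                ]
                X_test = build_feature_matrix(test_windows, list(fs), encoders)
                scores = predict_scores(predictor, X_test)
                pooled_scores.extend(float(s) for s in scores)
                pooled_labels.extend(w.label for w in test_windows)
                for w, s in zip(test_windows, scores):
                    chain = by_chain[w.chain_id][0]
                    preds.append(
                        {
                            "chain": w.chain_id,
                            "position": w.center,
                            "residue": chain.sequence[w.center - 1],
                            "score": float(s),
                            "label": w.label,
                            "fold": fold,
                        }
                    )
            report = evaluate_scores(np.array(pooled_scores), np.array(pooled_labels))
            thr = report.balanced_threshold
            for p in preds:
                p["call"] = int(p["score"] >= thr)
            reports[(fs_name, ratio)] = report
            predictions[(fs_name, ratio)] = preds

    result = ProtocolResult(reports=reports, predictions=predictions, run_log=log)
    if cfg.outdir:
        _write_outputs(result, cfg.outdir)
    return result


def _write_outputs(result: ProtocolResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(result.run_log, fh, indent=2)
    rows = ["feature_set\tratio\tauc\teer\tsensitivity\tspecificity\tprecision\taccuracy"]
    for (fs, ratio), rep in result.reports.items():
        rows.append(
            f"{fs}\t{ratio}\t{rep.auc:.4f}\t{rep.equal_error_rate:.4f}"
            f"\t{rep.sensitivity:.4f}\t{rep.specificity:.4f}"
            f"\t{rep.precision:.4f}\t{rep.accuracy:.4f}"
        )
    with open(os.path.join(outdir, "reports.tsv"), "w") as fh:
        fh.write("\n".join(rows) + "\n")
    for (fs, ratio), preds in result.predictions.items():
        safe = fs.replace("+", "_")
        path = os.path.join(outdir, f"predictions_{safe}_r{ratio}.tsv")
        with open(path, "w") as fh:
            fh.write("chain\tposition\tresidue\tscore\tcall\tlabel\tfold\n")
            for p in preds:
                fh.write(
                    f"{p['chain']}\t{p['position']}\t{p['residue']}"
                    f"\t{p['score']:.6f}\t{p['call']}\t{p['label']}\t{p['fold']}\n"
                )
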