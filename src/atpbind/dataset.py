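"""Training-set assembly: negative subsampling and chain-level CV folds.

Binding residues are heavily outnumbered by non-binding ones, so training
sets are built from all positives plus ``r`` times as many negatives drawn
uniformly without replacement (r = 1 gives the balanced set; larger r probes
the imbalance effect). Cross-validation folds are assigned at the chain
level, so all windows of a chain travel together and near-duplicate windows
from one chain can never straddle train and test; k equal to the number of
chains reproduces leave-one-out cross-validation over chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windowing import LabeledWindow

__all__ = ["SamplingPlan", "FoldAssignment", "subsample_negatives", "make_chain_folds"]


@dataclass(frozen=True)
class SamplingPlan:
    """Negative-to-positive ratio r and the seed for the draw."""

    ratio: int
    seed: int

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError(f"ratio must be >= 1, got {self.ratio}")


@dataclass(frozen=True)
class FoldAssignment:
    """A chain-id -> fold-index map partitioning the chain set into k folds."""

    fold_count: int
    assignment: dict[str, int]

    def test_chains(self, fold: int) -> frozenset[str]:
        return frozenset(c for c, f in self.assignment.items() if f == fold)

    def train_chains(self, fold: int) -> frozenset[str]:
        return frozenset(c for c, f in self.assignment.items() if f != fold)


def subsample_negatives(
    windows: list[LabeledWindow], plan: SamplingPlan
) -> list[LabeledWindow]:
    """Keep all positives plus min(r * n_pos, n_neg) random negatives.

    The draw is uniform without replacement and deterministic for a fixed
    seed. Output order: positives in input order, then the sampled negatives
    in input order.
    """
    positives = [w for w in windows if w.label == 1]
    negatives = [w for w in windows if w.label == 0]
    if not positives:
        raise ValueError("no positive windows; subsampling is undefined")
    n_keep = min(plan.ratio * len(positives), len(negatives))
    rng = np.random.default_rng(plan.seed)
    idx = rng.choice(len(negatives), size=n_keep, replace=False)
    kept = [negatives[i] for i in sorted(idx)]
    return positives + kept


def make_chain_folds(chain_ids: list[str], k: int, seed: int) -> FoldAssignment:
    """Shuffle chains with the seed, then deal them round-robin into k folds.

    Fold sizes differ by at most one; k == len(chain_ids) yields singleton
    folds (LOOCV over chains).
    """
    if len(set(chain_ids)) != len(chain_ids):
        raise ValueError("duplicate chain ids")
    if not 2 <= k <= len(chain_ids):
        raise ValueError(
            f"fold count must satisfy 2 <= k <= n_chains ({len(chain_ids)}), got {k}"
        )
    rng = np.random.default_rng(seed)
    order = list(chain_ids)
    rng.shuffle(order)
    return FoldAssignment(
        fold_count=k, assignment={cid: i % k for i, cid in enumerate(order)}
    )
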