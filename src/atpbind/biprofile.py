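"""Bi-profile Bayes posterior encoding and feature fusion.

Bi-profile sampling encodes a width-w window over a categorical track as a
2w-vector: positions 1..w hold the posterior probability of the observed
symbol at each position estimated from the *positive* training windows,
positions w+1..2w the same probabilities estimated from the *negative*
windows. A window whose symbols are typical of binding sites therefore gets
large values in the first half and small values in the second, and vice
versa — the classifier sees both class profiles at once.

Posteriors are per-position relative frequencies with optional
add-pseudocount smoothing (default 1); pseudocount 0 is the plain frequency
estimate. The amino-acid track's bi-profile is mathematically the bi-profile
sampling of the sparse 20-D one-hot residue encoding, so no separate raw
binary block exists.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .profiles_io import TRACK_ALPHABETS
from .windowing import PAD, LabeledWindow, pssm_window_vector

__all__ = [
    "BiProfileModel",
    "FeatureVector",
    "FeatureMatrix",
    "BLOCK_ORDER",
    "TRACK_FOR_BLOCK",
    "fit_biprofile",
    "encode_biprofile",
    "fuse_features",
    "build_feature_matrix",
]

# Alphabetic one-letter order (the order used for the one-hot residue code).
AA_ALPHABETICAL = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Closed encoder alphabets: track states + 'X' for nonstandard residues
#: (aa only) + the padding symbol.
ENCODER_ALPHABETS: dict[str, tuple[str, ...]] = {
    "aa": AA_ALPHABETICAL + ("X", PAD),
    "ss3": TRACK_ALPHABETS["ss3"] + (PAD,),
    "disorder2": TRACK_ALPHABETS["disorder2"] + (PAD,),
    "access2": TRACK_ALPHABETS["access2"] + (PAD,),
}

# Residue letters folded into the unknown symbol for the aa encoder.
_AA_FOLD = {c: "X" for c in "XBZUO"}

#: Canonical fusion order of feature blocks.
BLOCK_ORDER = ("LogisticPSSM", "Bipro-aa", "Bipro-ss", "Bipro-dis", "Bipro-sa")

#: Track kind encoded by each bi-profile block.
TRACK_FOR_BLOCK = {
    "Bipro-aa": "aa",
    "Bipro-ss": "ss3",
    "Bipro-dis": "disorder2",
    "Bipro-sa": "access2",
}


@dataclass
class BiProfileModel:
    """Positive and negative position x state posterior tables for one track."""

    track_kind: str
    alphabet: tuple[str, ...]
    w: int
    pos_table: np.ndarray
    neg_table: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        for name, table in (("pos", self.pos_table), ("neg", self.neg_table)):
            if table.shape != (self.w, len(self.alphabet)):
                raise ValueError(f"{name}_table shape {table.shape} != "
                                 f"({self.w}, {len(self.alphabet)})")
            if np.any(table < 0) or np.any(table > 1):
                raise ValueError(f"{name}_table entries must lie in [0, 1]")
            if self.pseudocount > 0 and not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name}_table rows must sum to 1")


def _window_symbols(win: LabeledWindow, track_kind: str) -> str:
    if track_kind == "aa":
        return "".join(_AA_FOLD.get(c, c) for c in win.aa_slice)
    try:
        return win.track_slices[track_kind]
    except KeyError as exc:
        raise ValueError(f"window lacks a {track_kind!r} track slice") from exc


def fit_biprofile(
    pos: list[LabeledWindow],
    neg: list[LabeledWindow],
    track_kind: str,
    pseudocount: float = 1.0,
) -> BiProfileModel:
    """Estimate per-position symbol posteriors from positive and negative windows.

    ``table[i, a] = (count of symbol a at position i + pseudocount) /
    (n_windows + pseudocount * |alphabet|)``.
    """
    if track_kind not in ENCODER_ALPHABETS:
        raise ValueError(f"unknown track kind {track_kind!r}")
    if not pos or not neg:
        raise ValueError("both positive and negative window sets must be nonempty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    widths = {w.width for w in pos} | {w.width for w in neg}
    if len(widths) != 1:
        raise ValueError(f"mixed window widths: {sorted(widths)}")
    (w,) = widths
    alphabet = ENCODER_ALPHABETS[track_kind]
    index = {a: j for j, a in enumerate(alphabet)}

    def table_for(windows: list[LabeledWindow]) -> np.ndarray:
        counts = np.zeros((w, len(alphabet)))
        for win in windows:
            symbols = _window_symbols(win, track_kind)
            for i, s in enumerate(symbols):
                try:
                    counts[i, index[s]] += 1
                except KeyError as exc:
                    raise ValueError(
                        f"symbol {s!r} outside the {track_kind} alphabet"
                    ) from exc
        return (counts + pseudocount) / (len(windows) + pseudocount * len(alphabet))

    return BiProfileModel(
        track_kind=track_kind,
        alphabet=alphabet,
        w=w,
        pos_table=table_for(pos),
        neg_table=table_for(neg),
        pseudocount=pseudocount,
    )


def encode_biprofile(win: LabeledWindow, model: BiProfileModel) -> np.ndarray:
    """Encode one window as its 2w-vector of positive and negative posteriors."""
    if win.width != model.w:
        raise ValueError(f"window width {win.width} != model width {model.w}")
    symbols = _window_symbols(win, model.track_kind)
    index = {a: j for j, a in enumerate(model.alphabet)}
    try:
        cols = [index[s] for s in symbols]
    except KeyError as exc:
        raise ValueError(
            f"window contains symbol outside the fitted alphabet: {exc}"
        ) from exc
    rows = np.arange(model.w)
    return np.concatenate([model.pos_table[rows, cols], model.neg_table[rows, cols]])


@dataclass
class FeatureVector:
    """Named, ordered feature blocks for one window."""

    blocks: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.blocks]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate block names: {names}")

    @property
    def total_dim(self) -> int:
        return sum(len(v) for _, v in self.blocks)

    @property
    def signature(self) -> tuple[tuple[str, int], ...]:
        return tuple((n, len(v)) for n, v in self.blocks)

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([v for _, v in self.blocks])


def _block_sort_key(name: str) -> int:
    try:
        return BLOCK_ORDER.index(name)
    except ValueError:
        return len(BLOCK_ORDER)


def fuse_features(blocks: list[tuple[str, np.ndarray]]) -> FeatureVector:
    """Concatenate named blocks in the canonical order.

    LogisticPSSM comes first, then bi-profile blocks in aa, ss, dis, sa
    order regardless of the order supplied.
    """
    if not blocks:
        raise ValueError("at least one feature block is required")
    ordered = sorted(
        [(n, np.asarray(v, dtype=float)) for n, v in blocks],
        key=lambda item: _block_sort_key(item[0]),
    )
    return FeatureVector(blocks=ordered)


@dataclass
class FeatureMatrix:
    """A stacked feature matrix plus the fusion signature it was built with."""

    values: np.ndarray
    signature: tuple[tuple[str, int], ...]

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.signature)


def build_feature_matrix(
    windows: list[LabeledWindow],
    block_names: list[str],
    encoders: dict[str, BiProfileModel] | None = None,
) -> FeatureMatrix:
    """Build the feature matrix for a window list and a named block set.

    ``block_names`` picks from ``BLOCK_ORDER``; each ``Bipro-*`` block needs
    a fitted :class:`BiProfileModel` in ``encoders`` keyed by track kind.
    """
    if not windows:
        raise ValueError("no windows supplied")
    unknown = [n for n in block_names if n not in BLOCK_ORDER]
    if unknown:
        raise ValueError(f"unknown feature blocks {unknown}; valid: {BLOCK_ORDER}")
    encoders = encoders or {}
    rows = []
    signature: tuple[tuple[str, int], ...] | None = None
    for win in windows:
        blocks: list[tuple[str, np.ndarray]] = []
        for name in block_names:
            if name == "LogisticPSSM":
                blocks.append((name, pssm_window_vector(win)))
            else:
                kind = TRACK_FOR_BLOCK[name]
                if kind not in encoders:
                    raise ValueError(f"no fitted bi-profile model for {name} ({kind})")
                blocks.append((name, encode_biprofile(win, encoders[kind])))
        fv = fuse_features(blocks)
        if signature is None:
            signature = fv.signature
        rows.append(fv.values)
    return FeatureMatrix(values=np.vstack(rows), signature=signature)
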