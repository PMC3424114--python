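"""Binding labels and fixed-width, center-labeled residue windows.

Every residue of a chain becomes the center of exactly one window of odd
width ``w`` (default 17, i.e. 8 residues to each side). Windows that run off
a chain terminus are padded: profile rows with the neutral normalized value
0.5 (the logistic image of a raw score of 0) and categorical/amino-acid
tracks with the dedicated padding symbol ``PAD``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles_io import (
    CategoricalTrack,
    ConsistencyError,
    ProfileMatrix,
    ProteinChain,
)

__all__ = [
    "PAD",
    "PAD_PROFILE_VALUE",
    "BindingAnnotation",
    "LabeledWindow",
    "load_binding_labels",
    "extract_windows",
    "pssm_window_vector",
]

#: Padding symbol for out-of-chain positions; a first-class alphabet member.
PAD = "□"  # '□'

#: Profile padding value: logistic(0), i.e. neutral evidence.
PAD_PROFILE_VALUE = 0.5


@dataclass(frozen=True)
class BindingAnnotation:
    """The set of 1-based binding-residue positions for one chain."""

    chain_id: str
    binding_positions: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "binding_positions", frozenset(self.binding_positions)
        )
        if any(p < 1 for p in self.binding_positions):
            raise ValueError("binding positions are 1-based and must be >= 1")


@dataclass
class LabeledWindow:
    """A width-w window of all tracks centered on one residue.

    ``center`` is 1-based. ``label`` is 1 when the center residue binds ATP.
    ``profile_slice`` is w x 20; ``aa_slice`` and each entry of
    ``track_slices`` are length-w strings over their alphabets plus ``PAD``.
    """

    chain_id: str
    center: int
    width: int
    label: int
    profile_slice: np.ndarray
    aa_slice: str
    track_slices: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width % 2 == 0 or self.width < 1:
            raise ValueError(f"window width must be odd and positive, got {self.width}")
        if len(self.aa_slice) != self.width:
            raise ValueError("aa_slice length differs from window width")

    @property
    def n_padded(self) -> int:
        return self.aa_slice.count(PAD)


def load_binding_labels(
    text: str, chains: dict[str, ProteinChain] | None = None
) -> dict[str, BindingAnnotation]:
    """Load a two-column ``chain_id<TAB>position`` TSV of binding residues.

    Duplicate lines collapse (set semantics). When ``chains`` is supplied,
    unknown chain ids and out-of-range positions are errors, and every known
    chain receives an annotation (possibly empty).
    """
    positions: dict[str, set[int]] = {}
    for lineno, raw in enumerate(text.replace("\r\n", "\n").split("\n"), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split("\t") if "\t" in line else line.split()
        if len(tokens) != 2:
            raise ValueError(f"line {lineno}: expected 'chain_id<TAB>position'")
        cid, pos_s = tokens
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: position {pos_s!r} is not an integer") from exc
        if pos < 1:
            raise ValueError(f"line {lineno}: positions are 1-based, got {pos}")
        positions.setdefault(cid, set()).add(pos)
    if chains is not None:
        unknown = sorted(set(positions) - set(chains))
        if unknown:
            raise ValueError(f"labels reference unknown chain ids: {unknown}")
        for cid, pos_set in positions.items():
            too_big = sorted(p for p in pos_set if p > chains[cid].length)
            if too_big:
                raise ValueError(
                    f"chain {cid!r} (length {chains[cid].length}): "
                    f"binding positions out of range: {too_big}"
                )
        for cid in chains:
            positions.setdefault(cid, set())
    return {
        cid: BindingAnnotation(chain_id=cid, binding_positions=frozenset(pos))
        for cid, pos in positions.items()
    }


def extract_windows(
    chain: ProteinChain,
    profile: ProfileMatrix,
    tracks: dict[str, CategoricalTrack],
    annotation: BindingAnnotation | None = None,
    w: int = 17,
) -> list[LabeledWindow]:
    """Cut one window per residue, padding at the termini.

    The profile must already be logistic-normalized (padding with 0.5 is
    only neutral on the normalized scale). Returns exactly ``chain.length``
    windows in residue order.
    """
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window width must be odd and positive, got {w}")
    if not profile.normalized:
        raise ValueError("profile must be logistic-normalized before windowing")
    if profile.length != chain.length:
        raise ConsistencyError("profile length differs from chain length")
    for kind, track in tracks.items():
        if track.length != chain.length:
            raise ConsistencyError(f"{kind} track length differs from chain length")
    binding = annotation.binding_positions if annotation is not None else frozenset()
    if binding and max(binding) > chain.length:
        raise ValueError("binding position beyond chain length")

    half = (w - 1) // 2
    n = chain.length
    # pre-pad the profile once; each window is then a contiguous slice
    padded = np.full((n + 2 * half, 20), PAD_PROFILE_VALUE)
    padded[half : half + n] = profile.values
    padded_aa = PAD * half + chain.sequence + PAD * half
    padded_tracks = {k: PAD * half + t.states + PAD * half for k, t in tracks.items()}

    windows = []
    for center in range(1, n + 1):
        lo = center - 1  # start index into the padded arrays
        windows.append(
            LabeledWindow(
                chain_id=chain.id,
                center=center,
                width=w,
                label=int(center in binding),
                profile_slice=padded[lo : lo + w].copy(),
                aa_slice=padded_aa[lo : lo + w],
                track_slices={k: s[lo : lo + w] for k, s in padded_tracks.items()},
            )
        )
    return windows


def pssm_window_vector(win: LabeledWindow) -> np.ndarray:
    """Flatten the window's profile slice position-major into a w*20 vector.

    At the default width 17 this is the 340-dimensional evolutionary-profile
    feature (LogisticPSSM).
    """
    if win.profile_slice is None:
        raise ValueError("window carries no profile slice")
    return np.asarray(win.profile_slice, dtype=float).reshape(-1)
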