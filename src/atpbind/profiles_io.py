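"""Parsers for per-residue feature files and profile normalization.

Four external per-residue formats feed the predictor:

* PSI-BLAST ASCII position-specific scoring matrices (the ``-Q`` matrix
  dump): one row of 20 log-odds scores per residue;
* PSIPRED ``.ss2`` three-state secondary-structure predictions;
* DISOPRED-style per-residue disorder output (mark + probability);
* SSpro-style two-state solvent-accessibility strings.

Raw log-odds profiles are squashed into (0, 1) with the logistic function
``ns = 1 / (1 + exp(-s))`` before windowing; everything downstream consumes
the normalized profile.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

__all__ = [
    "ProteinChain",
    "ProfileMatrix",
    "CategoricalTrack",
    "PSSM_COLUMNS",
    "TRACK_ALPHABETS",
    "FormatError",
    "ConsistencyError",
    "parse_pssm_ascii",
    "logistic_normalize",
    "parse_ss2",
    "parse_disorder",
    "parse_accessibility",
    "read_fasta_chains",
    "write_profile_bundle",
    "read_profile_bundle",
]

#: Fixed profile column order — the PSI-BLAST matrix header order.
PSSM_COLUMNS: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: Per-track state alphabets (padding handled by the windowing layer).
TRACK_ALPHABETS: dict[str, tuple[str, ...]] = {
    "ss3": ("H", "E", "C"),
    "disorder2": ("D", "O"),
    "access2": ("e", "b"),
}

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
# Nonstandard letters that PSI-BLAST / real sequence files may contain.
NONSTANDARD_AA = set("XBZUO")
VALID_AA = STANDARD_AA | NONSTANDARD_AA


class FormatError(ValueError):
    """A feature file deviates from its declared layout."""


class ConsistencyError(ValueError):
    """A parsed track disagrees with the supplied chain (length or residues)."""


@dataclass(frozen=True)
class ProteinChain:
    """A single protein chain identified by id, with its residue sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - VALID_AA
        if bad:
            raise ValueError(
                f"chain {self.id!r}: invalid residue letters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProfileMatrix:
    """An N x 20 evolutionary profile for one chain.

    ``values[i, j]`` is the (log-odds or logistic-normalized) score of
    residue ``i`` for amino acid ``PSSM_COLUMNS[j]``.
    """

    chain_id: str
    values: np.ndarray
    normalized: bool = False
    columns: tuple[str, ...] = PSSM_COLUMNS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(
                f"profile for {self.chain_id!r} must be N x 20, got {self.values.shape}"
            )
        if self.normalized and not (
            np.all(self.values > 0.0) and np.all(self.values < 1.0)
        ):
            raise ValueError("normalized profile values must lie strictly in (0, 1)")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class CategoricalTrack:
    """Per-residue categorical states for one chain and one track kind.

    ``kind`` is ``ss3`` (H/E/C), ``disorder2`` (D/O) or ``access2`` (e/b).
    ``probabilities`` optionally retains the source probabilities (one column
    per alphabet state for ss3, a single disorder probability for disorder2).
    """

    chain_id: str
    kind: str
    states: str
    probabilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in TRACK_ALPHABETS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        alphabet = set(TRACK_ALPHABETS[self.kind])
        bad = set(self.states) - alphabet
        if bad:
            raise ValueError(
                f"track {self.chain_id!r}/{self.kind}: symbols {sorted(bad)} "
                f"outside alphabet {sorted(alphabet)}"
            )

    @property
    def length(self) -> int:
        return len(self.states)


def _clean_lines(text: str) -> list[str]:
    # tolerate Windows line endings and trailing blank lines
    return text.replace("\r\n", "\n").replace("\r", "\n").split("\n")


def read_fasta_chains(source) -> list[ProteinChain]:
    """Read protein chains from a FASTA file path or handle."""
    if isinstance(source, str):
        handle = open(source)
    elif isinstance(source, io.IOBase):
        handle = source
    else:
        handle = io.StringIO(str(source))
    with handle:
        return [
            ProteinChain(id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(handle, "fasta")
        ]


def parse_pssm_ascii(text: str, chain: ProteinChain | None = None) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII matrix dump into an unnormalized profile.

    Only the first block of 20 columns (log-odds scores) is used; the
    weighted-percentage block that follows on each line is ignored. Row order
    follows the 1-based residue index in the file.

    Parameters
    ----------
    text:
        Full content of the ASCII matrix file.
    chain:
        If given, residue letters in the file are checked against the chain
        sequence and the row count against the chain length.
    """
    lines = _clean_lines(text)
    chain_id = chain.id if chain is not None else ""
    rows: list[list[float]] = []
    letters: list[str] = []
    in_body = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            if in_body:
                break  # blank line terminates the matrix body
            continue
        tokens = line.split()
        # the column-header line: 40 (or 20) amino-acid letters
        if not in_body and all(t in STANDARD_AA for t in tokens) and len(tokens) >= 20:
            in_body = True
            continue
        if not in_body:
            continue
        if not tokens[0].lstrip("-").isdigit():
            break  # footer (K/lambda lines etc.)
        if len(tokens) < 22:
            raise FormatError(
                f"line {lineno}: expected index, residue and >=20 scores, "
                f"got {len(tokens)} fields: {line!r}"
            )
        residue = tokens[1].upper()
        if residue not in VALID_AA:
            raise FormatError(f"line {lineno}: invalid residue letter {tokens[1]!r}")
        try:
            scores = [float(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric score in {line!r}") from exc
        rows.append(scores)
        letters.append(residue)
    if not rows:
        raise FormatError("no matrix body found in PSI-BLAST ASCII input")
    if chain is not None:
        if len(rows) != chain.length:
            raise ConsistencyError(
                f"profile has {len(rows)} rows but chain {chain.id!r} "
                f"has {chain.length} residues"
            )
        for i, (a, b) in enumerate(zip(letters, chain.sequence), start=1):
            if a != b:
                raise ConsistencyError(
                    f"residue mismatch at position {i}: profile says {a!r}, "
                    f"chain {chain.id!r} says {b!r}"
                )
    return ProfileMatrix(chain_id=chain_id, values=np.array(rows), normalized=False)


def logistic_normalize(m: ProfileMatrix) -> ProfileMatrix:
    """Map every raw score s to 1 / (1 + exp(-s)).

    The result lives strictly in (0, 1); a raw score of 0 maps to 0.5.
    Applying the transform twice would silently compress the profile, so
    already-normalized input is rejected.
    """
    if m.normalized:
        raise ValueError("profile is already logistic-normalized")
    with np.errstate(over="ignore"):
        values = 1.0 / (1.0 + np.exp(-m.values))
    # guard against exact 0/1 from extreme scores (keeps the open-interval
    # invariant; float eps is far below any biological signal)
    tiny = np.finfo(float).tiny
    values = np.clip(values, tiny, 1.0 - np.finfo(float).epsneg)
    return replace(m, values=values, normalized=True)


def parse_ss2(text: str, chain: ProteinChain | None = None) -> CategoricalTrack:
    """Parse PSIPRED ``.ss2`` output into a three-state track.

    Each data line carries ``index residue state p_coil p_helix p_strand``.
    The state letter column is authoritative; probabilities are retained in
    (C, H, E) file order re-indexed to the (H, E, C) alphabet order.
    """
    states: list[str] = []
    probs: list[list[float]] = []
    for lineno, raw in enumerate(_clean_lines(text), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 6 or not tokens[0].isdigit():
            raise FormatError(f"line {lineno}: malformed .ss2 line {line!r}")
        state = tokens[2].upper()
        if state not in TRACK_ALPHABETS["ss3"]:
            raise FormatError(f"line {lineno}: unknown SS state {tokens[2]!r}")
        try:
            p_c, p_h, p_e = (float(t) for t in tokens[3:6])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric probability") from exc
        if abs((p_c + p_h + p_e) - 1.0) > 0.05:
            warnings.warn(
                f".ss2 line {lineno}: probabilities sum to {p_c + p_h + p_e:.3f}",
                stacklevel=2,
            )
        states.append(state)
        probs.append([p_h, p_e, p_c])  # alphabet order H, E, C
    track = CategoricalTrack(
        chain_id=chain.id if chain else "",
        kind="ss3",
        states="".join(states),
        probabilities=np.array(probs) if probs else None,
    )
    _check_length(track, chain)
    return track


def parse_disorder(text: str, chain: ProteinChain | None = None) -> CategoricalTrack:
    """Parse DISOPRED-style per-residue output into a two-state track.

    Lines carry ``index residue mark probability`` where the mark is ``*``
    (disordered) or ``.``. Binarization uses the probability when present:
    state D iff p >= 0.5 (ties to disordered); otherwise the mark decides.
    """
    states: list[str] = []
    probs: list[float] = []
    for lineno, raw in enumerate(_clean_lines(text), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 3 or not tokens[0].isdigit():
            raise FormatError(f"line {lineno}: malformed disorder line {line!r}")
        prob: float | None = None
        if len(tokens) >= 4:
            try:
                prob = float(tokens[3])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric probability") from exc
            if not 0.0 <= prob <= 1.0:
                raise FormatError(
                    f"line {lineno}: disorder probability {prob} outside [0, 1]"
                )
            states.append("D" if prob >= 0.5 else "O")
        else:
            mark = tokens[2]
            if mark not in {"*", "."}:
                raise FormatError(f"line {lineno}: unknown disorder mark {mark!r}")
            prob = 1.0 if mark == "*" else 0.0
            states.append("D" if mark == "*" else "O")
        probs.append(prob)
    track = CategoricalTrack(
        chain_id=chain.id if chain else "",
        kind="disorder2",
        states="".join(states),
        probabilities=np.array(probs) if probs else None,
    )
    _check_length(track, chain)
    return track


_ACCESS_CANON = {"e": "e", "E": "e", "b": "b", "B": "b", "-": "b"}


def parse_accessibility(text: str, chain: ProteinChain | None = None) -> CategoricalTrack:
    """Parse an SSpro-style two-state accessibility string.

    Accepts the ``e``/``b`` dialect in either case and ``-`` for buried;
    whitespace and line breaks between symbols are ignored, so both a single
    string and a one-symbol-per-line file parse.
    """
    symbols = [c for c in text if not c.isspace()]
    states = []
    for pos, c in enumerate(symbols, start=1):
        if c not in _ACCESS_CANON:
            raise FormatError(f"position {pos}: unknown accessibility symbol {c!r}")
        states.append(_ACCESS_CANON[c])
    track = CategoricalTrack(
        chain_id=chain.id if chain else "", kind="access2", states="".join(states)
    )
    _check_length(track, chain)
    return track


def _check_length(track: CategoricalTrack, chain: ProteinChain | None) -> None:
    if chain is not None and track.length != chain.length:
        raise ConsistencyError(
            f"{track.kind} track has {track.length} states but chain "
            f"{chain.id!r} has {chain.length} residues"
        )


# --------------------------------------------------------------------------
# Canonical per-chain profile bundle: a single TSV holding every track.

BUNDLE_HEADER = (
    ["position", "residue"]
    + [f"p_{a}" for a in PSSM_COLUMNS]
    + ["ss", "disorder", "access"]
)


def write_profile_bundle(
    path: str,
    chain: ProteinChain,
    profile: ProfileMatrix,
    tracks: dict[str, CategoricalTrack],
) -> None:
    """Write one chain's profile and categorical tracks as a canonical TSV."""
    for kind in ("ss3", "disorder2", "access2"):
        if kind not in tracks:
            raise ValueError(f"missing {kind} track for bundle")
    if profile.length != chain.length:
        raise ConsistencyError("profile length does not match chain length")
    with open(path, "w") as fh:
        fh.write(f"# chain: {chain.id}\n")
        fh.write(f"# normalized: {int(profile.normalized)}\n")
        fh.write("\t".join(BUNDLE_HEADER) + "\n")
        for i in range(chain.length):
            row = [str(i + 1), chain.sequence[i]]
            row += [format(v, ".6g") for v in profile.values[i]]
            row += [
                tracks["ss3"].states[i],
                tracks["disorder2"].states[i],
                tracks["access2"].states[i],
            ]
            fh.write("\t".join(row) + "\n")


def read_profile_bundle(
    path: str,
) -> tuple[ProteinChain, ProfileMatrix, dict[str, CategoricalTrack]]:
    """Read a canonical profile bundle written by :func:`write_profile_bundle`."""
    chain_id = ""
    normalized = False
    seq: list[str] = []
    values: list[list[float]] = []
    ss: list[str] = []
    dis: list[str] = []
    acc: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("# chain:"):
                chain_id = line.split(":", 1)[1].strip()
                continue
            if line.startswith("# normalized:"):
                normalized = bool(int(line.split(":", 1)[1]))
                continue
            if line.startswith("position\t"):
                continue
            tokens = line.split("\t")
            if len(tokens) != len(BUNDLE_HEADER):
                raise FormatError(f"bundle row has {len(tokens)} fields: {line!r}")
            seq.append(tokens[1])
            values.append([float(t) for t in tokens[2:22]])
            ss.append(tokens[22])
            dis.append(tokens[23])
            acc.append(tokens[24])
    chain = ProteinChain(id=chain_id, sequence="".join(seq))
    arr = np.array(values)
    if normalized:
        # written at finite precision; restore the open-interval invariant
        arr = np.clip(arr, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    profile = ProfileMatrix(chain_id=chain_id, values=arr, normalized=normalized)
    tracks = {
        "ss3": CategoricalTrack(chain_id, "ss3", "".join(ss)),
        "disorder2": CategoricalTrack(chain_id, "disorder2", "".join(dis)),
        "access2": CategoricalTrack(chain_id, "access2", "".join(acc)),
    }
    return chain, profile, tracks
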