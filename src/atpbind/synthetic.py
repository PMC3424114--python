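"""Seed-reproducible synthetic chains, profiles, tracks and binding labels.

The generator emulates the external inputs the predictor consumes — FASTA
chains, PSI-BLAST ASCII profiles, PSIPRED ``.ss2``, DISOPRED output,
accessibility strings and a binding-label TSV — with class-dependent
structure: binding residues receive a mean shift on designated profile
columns (by default the P-loop-flavored G, K, S, T) and draw their
categorical states from class-specific rates.

Defaults mirror the class-conditional state frequencies observed in real
ATP-binding chains: binding residues are almost always ordered (2% vs 8.1%
disordered), predominantly buried (75.3% vs 58.5%), and coil-enriched /
helix-depleted (C/H/E 49.6/26.0/24.4% vs 41.7/40.3/18.0%). Files written by
:func:`write_dataset` round-trip through the real parsers, so the whole
pipeline can run without any external database or predictor.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .profiles_io import (
    PSSM_COLUMNS,
    CategoricalTrack,
    ProfileMatrix,
    ProteinChain,
    logistic_normalize,
)
from .windowing import BindingAnnotation

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_synthetic_dataset", "write_dataset"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Columns whose raw log-odds mean is shifted at binding residues
#: (the Walker-A / P-loop motif residues glycine, lysine, serine, threonine).
DEFAULT_SHIFT_COLUMNS: tuple[str, ...] = ("G", "K", "S", "T")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    ``ss_center_probs_*`` are (C, H, E) simplex vectors for the secondary-
    structure state of binding (pos) and non-binding (neg) residues;
    ``disorder_rate_*`` and ``buried_rate_*`` are the per-class Bernoulli
    rates of the D and b states. ``pssm_shift`` is the mean raw log-odds
    shift added on ``shift_columns`` for residues within ``shift_radius``
    of a binding position (conservation around a binding motif extends over
    its neighborhood, as it does in real profiles).
    """

    n_chains: int = 30
    length_range: tuple[int, int] = (60, 120)
    binding_fraction: float = 0.05
    pssm_shift: float = 2.0
    shift_columns: tuple[str, ...] = DEFAULT_SHIFT_COLUMNS
    shift_radius: int = 2
    ss_center_probs_pos: tuple[float, float, float] = (0.496, 0.260, 0.244)
    ss_center_probs_neg: tuple[float, float, float] = (0.417, 0.403, 0.180)
    disorder_rate_pos: float = 0.02
    disorder_rate_neg: float = 0.081
    buried_rate_pos: float = 0.753
    buried_rate_neg: float = 0.585
    pssm_sd: float = 2.0
    min_spacing: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be positive")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"bad length_range {self.length_range}")
        if not 0.0 < self.binding_fraction < 1.0:
            raise ValueError("binding_fraction must lie strictly in (0, 1)")
        for name in ("disorder_rate_pos", "disorder_rate_neg",
                     "buried_rate_pos", "buried_rate_neg"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        for name in ("ss_center_probs_pos", "ss_center_probs_neg"):
            p = getattr(self, name)
            if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a 3-simplex vector, got {p}")
        if self.shift_radius < 0:
            raise ValueError("shift_radius must be nonnegative")
        bad = set(self.shift_columns) - set(PSSM_COLUMNS)
        if bad:
            raise ValueError(f"shift_columns not in profile alphabet: {sorted(bad)}")
        if lo < 17:
            import warnings

            warnings.warn(
                f"minimum chain length {lo} is below the default window width 17; "
                "terminal padding will dominate short chains",
                stacklevel=2,
            )


@dataclass
class SyntheticDataset:
    """In-memory view of one generated dataset (raw and normalized profiles)."""

    spec: SyntheticSpec
    chains: list[ProteinChain]
    raw_profiles: dict[str, ProfileMatrix]
    profiles: dict[str, ProfileMatrix]  # logistic-normalized
    tracks: dict[str, dict[str, CategoricalTrack]]  # chain_id -> kind -> track
    annotations: dict[str, BindingAnnotation]
    ss_probs: dict[str, np.ndarray] = field(default_factory=dict)
    disorder_probs: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_binding(self) -> int:
        return sum(len(a.binding_positions) for a in self.annotations.values())

    @property
    def n_residues(self) -> int:
        return sum(c.length for c in self.chains)


def _draw_binding_positions(
    rng: np.random.Generator, n: int, fraction: float, min_spacing: int
) -> frozenset[int]:
    k = max(1, int(round(fraction * n)))
    if min_spacing <= 0:
        picks = rng.choice(n, size=k, replace=False) + 1
        return frozenset(int(p) for p in picks)
    chosen: list[int] = []
    for pos in rng.permutation(n) + 1:
        if all(abs(pos - c) >= min_spacing for c in chosen):
            chosen.append(int(pos))
        if len(chosen) == k:
            break
    return frozenset(chosen)


def generate_synthetic_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate chains, profiles, tracks and labels under the spec's conditions.

    Residues are drawn uniformly over the 20 standard amino acids. Raw
    profile scores are integer-rounded normal draws (sd ``pssm_sd``) with
    the mean on ``shift_columns`` raised by ``pssm_shift`` at binding
    residues, matching the integer log-odds dialect of PSI-BLAST ASCII
    output. Deterministic for a fixed spec (the seed is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    shift_idx = [PSSM_COLUMNS.index(c) for c in spec.shift_columns]
    ss_letters = np.array(list("CHE"))
    chains: list[ProteinChain] = []
    raw_profiles: dict[str, ProfileMatrix] = {}
    profiles: dict[str, ProfileMatrix] = {}
    tracks: dict[str, dict[str, CategoricalTrack]] = {}
    annotations: dict[str, BindingAnnotation] = {}
    ss_probs: dict[str, np.ndarray] = {}
    disorder_probs: dict[str, np.ndarray] = {}

    lo, hi = spec.length_range
    for i in range(spec.n_chains):
        cid = f"syn{i:04d}"
        n = int(rng.integers(lo, hi + 1))
        sequence = "".join(rng.choice(list(AA20), size=n))
        chain = ProteinChain(id=cid, sequence=sequence)
        binding = _draw_binding_positions(rng, n, spec.binding_fraction, spec.min_spacing)
        is_pos = np.array([(p + 1) in binding for p in range(n)])

        near_pos = np.zeros(n, dtype=bool)
        for b in binding:
            lo_i = max(0, b - 1 - spec.shift_radius)
            near_pos[lo_i : b + spec.shift_radius] = True
        raw = rng.normal(0.0, spec.pssm_sd, size=(n, 20))
        raw[np.ix_(near_pos, shift_idx)] += spec.pssm_shift
        raw = np.rint(raw)
        raw_m = ProfileMatrix(chain_id=cid, values=raw, normalized=False)

        ss_p = np.where(
            is_pos[:, None],
            np.asarray(spec.ss_center_probs_pos),
            np.asarray(spec.ss_center_probs_neg),
        )
        ss_states = np.array([str(rng.choice(ss_letters, p=p)) for p in ss_p])
        dis_rate = np.where(is_pos, spec.disorder_rate_pos, spec.disorder_rate_neg)
        dis_draw = rng.random(n) < dis_rate
        # emit probabilities consistent with the binarized state so the
        # DISOPRED dialect round-trips exactly
        dis_p = np.where(dis_draw, 0.5 + 0.5 * rng.random(n), 0.49 * rng.random(n))
        bur_rate = np.where(is_pos, spec.buried_rate_pos, spec.buried_rate_neg)
        acc_states = np.where(rng.random(n) < bur_rate, "b", "e")

        # ss3 probabilities: sharp toward the drawn state (for the .ss2 file)
        conf = 0.6 + 0.3 * rng.random(n)
        ss_file_probs = np.full((n, 3), 0.0)  # file order C, H, E
        for j, s in enumerate(ss_states):
            rest = (1.0 - conf[j]) / 2.0
            ss_file_probs[j] = rest
            ss_file_probs[j, "CHE".index(s)] = conf[j]

        chains.append(chain)
        raw_profiles[cid] = raw_m
        profiles[cid] = logistic_normalize(raw_m)
        tracks[cid] = {
            "ss3": CategoricalTrack(cid, "ss3", "".join(ss_states)),
            "disorder2": CategoricalTrack(
                cid, "disorder2", "".join("D" if d else "O" for d in dis_draw),
                probabilities=dis_p,
            ),
            "access2": CategoricalTrack(cid, "access2", "".join(acc_states)),
        }
        annotations[cid] = BindingAnnotation(chain_id=cid, binding_positions=binding)
        ss_probs[cid] = ss_file_probs
        disorder_probs[cid] = dis_p

    return SyntheticDataset(
        spec=spec,
        chains=chains,
        raw_profiles=raw_profiles,
        profiles=profiles,
        tracks=tracks,
        annotations=annotations,
        ss_probs=ss_probs,
        disorder_probs=disorder_probs,
    )


# --------------------------------------------------------------------------
# Writers in the external file dialects (consumed back by profiles_io).

_PSSM_HEADER = (
    "\nLast position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts\n"
)


def format_pssm_ascii(chain: ProteinChain, profile: ProfileMatrix) -> str:
    """Render a raw profile in the PSI-BLAST ASCII matrix dialect."""
    if profile.normalized:
        raise ValueError("write the raw (unnormalized) profile")
    out = [_PSSM_HEADER]
    letters = "  ".join(PSSM_COLUMNS)
    out.append(f"            {letters}   {letters}\n")
    for i in range(chain.length):
        scores = "".join(f"{int(v):4d}" for v in profile.values[i])
        pcts = "".join(f"{0:4d}" for _ in range(20))
        out.append(f"{i + 1:5d} {chain.sequence[i]}  {scores} {pcts}  0.00 0.00\n")
    out.append("\n")
    return "".join(out)


def format_ss2(chain: ProteinChain, states: str, probs: np.ndarray) -> str:
    out = ["# PSIPRED VFORMAT (PSIPRED V4.0)\n", "\n"]
    for i in range(chain.length):
        c, h, e = probs[i]
        out.append(
            f"{i + 1:4d} {chain.sequence[i]} {states[i]}  {c:6.3f} {h:6.3f} {e:6.3f}\n"
        )
    return "".join(out)


def format_disorder(chain: ProteinChain, states: str, probs: np.ndarray) -> str:
    out = []
    for i in range(chain.length):
        mark = "*" if states[i] == "D" else "."
        out.append(f"{i + 1:5d} {chain.sequence[i]} {mark} {probs[i]:.2f}\n")
    return "".join(out)


def write_dataset(ds: SyntheticDataset, outdir: str) -> dict[str, str]:
    """Write the dataset in all external dialects; returns the path map.

    Layout: ``chains.fasta``, ``labels.tsv`` and per-chain ``<id>.pssm``,
    ``<id>.ss2``, ``<id>.diso``, ``<id>.acc`` under ``profiles/``.
    """
    os.makedirs(outdir, exist_ok=True)
    prof_dir = os.path.join(outdir, "profiles")
    os.makedirs(prof_dir, exist_ok=True)
    fasta = os.path.join(outdir, "chains.fasta")
    with open(fasta, "w") as fh:
        for chain in ds.chains:
            fh.write(f">{chain.id}\n")
            for i in range(0, chain.length, 60):
                fh.write(chain.sequence[i : i + 60] + "\n")
    labels = os.path.join(outdir, "labels.tsv")
    with open(labels, "w") as fh:
        for chain in ds.chains:
            for pos in sorted(ds.annotations[chain.id].binding_positions):
                fh.write(f"{chain.id}\t{pos}\n")
    for chain in ds.chains:
        cid = chain.id
        with open(os.path.join(prof_dir, f"{cid}.pssm"), "w") as fh:
            fh.write(format_pssm_ascii(chain, ds.raw_profiles[cid]))
        with open(os.path.join(prof_dir, f"{cid}.ss2"), "w") as fh:
            fh.write(format_ss2(chain, ds.tracks[cid]["ss3"].states, ds.ss_probs[cid]))
        with open(os.path.join(prof_dir, f"{cid}.diso"), "w") as fh:
            fh.write(
                format_disorder(
                    chain, ds.tracks[cid]["disorder2"].states, ds.disorder_probs[cid]
                )
            )
        with open(os.path.join(prof_dir, f"{cid}.acc"), "w") as fh:
            fh.write(ds.tracks[cid]["access2"].states + "\n")
    return {"fasta": fasta, "labels": labels, "profiles": prof_dir}
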