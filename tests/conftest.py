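import numpy as np
import pytest

from atpbind import LabeledWindow, ProteinChain, PSSM_COLUMNS


def make_window(
    symbols: str,
    kind: str = "ss3",
    label: int = 0,
    chain_id: str = "c1",
    center: int = 1,
    profile_value: float = 0.5,
) -> LabeledWindow:
    """Build a minimal window whose given track slice is `symbols`."""
    w = len(symbols)
    aa = "A" * w if kind != "aa" else symbols
    return LabeledWindow(
        chain_id=chain_id,
        center=center,
        width=w,
        label=label,
        profile_slice=np.full((w, 20), profile_value),
        aa_slice=aa,
        track_slices={} if kind == "aa" else {kind: symbols},
    )


def pssm_text(sequence: str, values) -> str:
    """Render raw integer scores in the PSI-BLAST ASCII matrix dialect."""
    values = np.asarray(values)
    header = "  ".join(PSSM_COLUMNS)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        f"            {header}   {header}",
    ]
    for i, aa in enumerate(sequence):
        scores = "".join(f"{int(v):4d}" for v in values[i])
        pcts = "".join(f"{0:4d}" for _ in range(20))
        lines.append(f"{i + 1:5d} {aa}  {scores} {pcts}  0.00 0.00")
    lines.append("")
    return "\n".join(lines)


@pytest.fixture
def toy_chain() -> ProteinChain:
    return ProteinChain(id="toy", sequence="MKVLA")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
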