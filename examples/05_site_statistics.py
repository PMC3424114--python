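"""Descriptive statistics of binding vs non-binding residues.

Prints (1) positional state frequencies across the 17-residue window around
binding sites — offset 0 is the binding residue — and (2) the per-class
composition table (percent ordered/disordered, coil/helix/strand,
exposed/buried). With the default generator the binding class is ordered,
buried and coil-enriched, the pattern seen in real protein-ATP interfaces.
"""

from atpbind import (
    SyntheticSpec,
    extract_windows,
    generate_synthetic_dataset,
    positional_state_frequencies,
    site_composition_table,
)

ds = generate_synthetic_dataset(
    SyntheticSpec(n_chains=40, length_range=(80, 120), binding_fraction=0.1, seed=3)
)
positives = []
for chain in ds.chains:
    positives += [
        w
        for w in extract_windows(
            chain, ds.profiles[chain.id], ds.tracks[chain.id], ds.annotations[chain.id]
        )
        if w.label == 1
    ]
print(f"{len(positives)} binding-centered windows\n")

freq = positional_state_frequencies(positives, "disorder2")
print("P(disordered) by offset from the binding site:")
for offset in (-8, -4, -1, 0, 1, 4, 8):
    print(f"  {offset:+d}: {freq.frequency(offset, 'D'):.3f}")

tracks = [t for per_chain in ds.tracks.values() for t in per_chain.values()]
table = site_composition_table(tracks, ds.annotations)
print("\ncomposition (%) by class:")
print(table.round(1).to_string())
# The disorder dip at offset 0 and the buried excess in the binding column
# mirror the class-conditional rates the generator was given.
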