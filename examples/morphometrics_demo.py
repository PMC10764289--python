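"""Tissue-scale quantifications: filopodia, cell shape, paracrine signalling.

Classifies membrane protrusions as filopodia, bins their lengths, computes
cell circularity, and measures a paracrine signalling halo around a
signal-producing clone with the kinase-translocation-reporter (KTR) call:
a cell whose reporter is excluded from the nucleus
(nuclear/cytoplasmic < 1) is scored active.
"""

from cytofccs import (
    CellShape,
    ProtrusionRecord,
    bin_lengths,
    circularity,
    classify_filopodium,
    generate_cell_grid,
    ktr_activity,
    paracrine_profile,
)

protrusions = [
    ProtrusionRecord(length=12.5, width=1.1),
    ProtrusionRecord(length=3.0, width=1.4),
    ProtrusionRecord(length=0.8, width=1.0),  # too short to count
    ProtrusionRecord(length=25.0, width=1.2),
]
filopodia = [p for p in protrusions if classify_filopodium(p)]
print(f"{len(filopodia)} of {len(protrusions)} protrusions are filopodia (>= 1 µm)")
print(bin_lengths([p.length for p in filopodia], [0, 5, 10, 20, 50]).to_string(index=False))

round_cell = CellShape(area=78.5, perimeter=31.5)
stretched = CellShape(area=78.5, perimeter=62.8)
print(f"\ncircularity: round cell {circularity(round_cell):.2f}, "
      f"stretched cell {circularity(stretched):.2f}")

ratio, active = ktr_activity(nuclear=30.0, cytoplasmic=100.0)
print(f"\nKTR call: nuclear/cytoplasmic = {ratio:.2f} -> "
      f"{'active' if active else 'inactive'}")

# A clone at the grid centre activates its neighbours with probability
# decaying over five cell rows.
grid = generate_cell_grid(
    21, 21, [(10, 10)], {1: 0.9, 2: 0.7, 3: 0.5, 4: 0.3, 5: 0.15}, seed=4
)
print("\nparacrine activation profile (fraction of active cells per row):")
print(paracrine_profile(grid).to_string(index=False))
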