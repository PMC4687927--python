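"""The consolidation layer alone, on a hand-built window label track.

Seven runs of consecutive tm windows are detected as stretches; the long
hairpin run (windows 31..53, covering residues 31..62) is split into two
~13-residue sub-regions; candidate boundaries are enumerated from window
termini and ranked by the boundary preference scores.
"""

from barreltm import (
    PreferenceTable,
    ProteinSequence,
    enumerate_subsegments,
    find_stretches,
    predict_from_labels,
    split_stretch,
    stretch_span,
)
from barreltm.dataset import NTM, TM
from barreltm.encoding import AMINO_ACIDS

labels = [NTM] * 162
for first, last in [(4, 11), (31, 53), (70, 80), (89, 96),
                    (117, 124), (132, 140), (156, 162)]:
    for w in range(first, last + 1):
        labels[w - 1] = TM

stretches = find_stretches(labels)
print(f"{len(stretches)} stretches of >= 4 consecutive tm windows:")
for s in stretches:
    span = stretch_span(s)
    pieces = split_stretch(span)
    n_cand = sum(len(enumerate_subsegments(s, None if len(pieces) == 1 else p))
                 for p in pieces)
    print(f"  windows {s.first_window}..{s.last_window} -> residues "
          f"{span[0]}..{span[1]} ({len(pieces)} sub-region(s), "
          f"{n_cand} candidate boundaries)")

# with a flat positive preference table every stretch reports one region
# (two for the split hairpin): 8 regions, matching an 8-stranded barrel
flat = PreferenceTable({a: 1.0 for a in AMINO_ACIDS}, {a: 1.0 for a in AMINO_ACIDS})
seq = ProteinSequence("demo", ("ADGKLVWYEF" * 18)[:171])
regions = predict_from_labels(seq, labels, flat)
print(f"\nreported regions ({len(regions)}):",
      [(r.start, r.end) for r in regions])
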