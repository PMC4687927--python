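"""Sliding-window segmentation and pair-frequency encoding of one protein.

A protein of n residues yields n-9 overlapping 10-residue windows; each
window is encoded by its 20x20 amino-acid adjacency matrix flattened to a
400-entry count vector whose entries always sum to 9 (window length - 1).
"""

from barreltm import ProteinSequence, adjacency_matrix, descriptor_vector, segment_protein

seq = ProteinSequence("demo", "MKKTAIAIAVALAGFATVAQAAPKDNTWYTGAKLGWSQYHDTGFINNNGPTHENQLGAGAFGGYQVNPYVGFEMGYDWLGRMPYKGSVENGAYKAQGVQLTAKLGYPITDDLDIYTRLGGMVWRADTKSNVYGKNHDTGVSPVFAGGVEYAIT"[:60])

windows = segment_protein(seq, w=10)
print(f"protein {seq.id}: {seq.n} residues -> {len(windows)} windows of 10")

first = windows[0]
vec = descriptor_vector(first.sequence)
print(f"window 1 covers residues {first.start}..{first.end}: {first.sequence}")
print(f"descriptor: {vec.shape[0]} entries, {int((vec > 0).sum())} non-zero, sum {int(vec.sum())}")

mat = adjacency_matrix(first.sequence)
print(f"adjacency matrix total pair count: {int(mat.sum())} (= window length - 1)")
# every window's descriptor depends only on its own 10 residues, so the
# same subsequence anywhere in any protein encodes identically
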