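"""Sliding-window segmentation and amino-acid pair-frequency encoding.

A protein is cut into overlapping windows of ``w`` residues (step 1), and each
window is encoded by its 20x20 amino-acid adjacency matrix: entry (a, b)
counts how often residue ``a`` is immediately followed (N-to-C) by residue
``b`` within the window.  Row-major flattening of that matrix gives the
400-dimensional descriptor used by the strand/loop classifier.  The 20-entry
row-sum marginal (plain residue counts) is provided only as a deliberately
information-losing baseline for comparison experiments; it discards the
adjacency information that carries the local sequence pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 standard amino acids, alphabetical one-letter order.  This ordering
#: fixes the descriptor layout and must never change (model portability).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Version tag for the descriptor layout; persisted models refuse to predict
#: when the tag of the encoder that produced their training data differs.
ENCODING_VERSION = "aa-pairs-rowmajor-v1"

DESCRIPTOR_DIM = 400

#: Ambiguity-code normalization: B (Asx) -> N, Z (Glx) -> Q, U (Sec) -> C.
AMBIGUITY_MAP = {"B": "N", "Z": "Q", "U": "C"}


class SequenceTooShortError(ValueError):
    """Raised when a sequence is shorter than the window length."""


class UnknownResidueError(ValueError):
    """Raised when a residue cannot be mapped to a standard amino acid."""


def normalize_sequence(residues: str, *, allow_x: bool = False) -> str:
    """Upper-case a sequence and map ambiguity codes onto standard residues.

    B, Z and U are rewritten to N, Q and C.  Any other non-standard character
    raises :class:`UnknownResidueError` naming the character and its 1-based
    position, unless ``allow_x`` is set, in which case ``X`` is kept verbatim
    (pairs involving X are then skipped during counting).
    """
    out = []
    for pos, ch in enumerate(residues.upper(), start=1):
        ch = AMBIGUITY_MAP.get(ch, ch)
        if ch in AA_INDEX or (allow_x and ch == "X"):
            out.append(ch)
        else:
            raise UnknownResidueError(
                f"unknown residue {ch!r} at position {pos}"
            )
    return "".join(out)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with a free-text identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    @property
    def n(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SegmentWindow:
    """A window of a parent protein; ``start``/``end`` are 1-based inclusive."""

    parent_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("window coordinates inconsistent with sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


def segment_protein(seq: ProteinSequence, w: int = 10) -> list[SegmentWindow]:
    """Cut ``seq`` into its n-w+1 overlapping windows of length ``w`` (step 1).

    Consecutive windows share w-1 residues.  A sequence shorter than ``w``
    raises :class:`SequenceTooShortError`.
    """
    n = seq.n
    if n < w:
        raise SequenceTooShortError(
            f"protein {seq.id!r}: sequence of {n} residues is shorter than "
            f"the window length; at least {w} residues are required"
        )
    return [
        SegmentWindow(seq.id, i + 1, i + w, seq.residues[i : i + w])
        for i in range(n - w + 1)
    ]


def adjacency_matrix(segment: str, *, allow_x: bool = False) -> np.ndarray:
    """20x20 ordered-pair count matrix of a segment string.

    Entry (a, b) counts occurrences of residue ``a`` immediately followed by
    ``b`` reading N to C.  The matrix total equals ``len(segment) - 1``
    (minus any pairs skipped because they involve X under ``allow_x``).
    """
    if len(segment) < 2:
        raise ValueError(
            f"segment of length {len(segment)} too short to encode; "
            "at least 2 residues required"
        )
    norm = normalize_sequence(segment, allow_x=allow_x)
    mat = np.zeros((20, 20), dtype=np.int64)
    for a, b in zip(norm, norm[1:]):
        if a == "X" or b == "X":
            continue
        mat[AA_INDEX[a], AA_INDEX[b]] += 1
    return mat


def descriptor_vector(segment: str, *, allow_x: bool = False) -> np.ndarray:
    """Row-major flattening of :func:`adjacency_matrix` (400 counts).

    Pure function of the segment string: the same subsequence yields an
    identical vector regardless of where in a protein it occurs.
    """
    return adjacency_matrix(segment, allow_x=allow_x).reshape(DESCRIPTOR_DIM)


def rowsum_descriptor(segment: str, *, allow_x: bool = False) -> np.ndarray:
    """20-entry row-sum marginal of the adjacency matrix.

    Counts each residue's occurrences as the first member of a pair, i.e. the
    composition of the segment minus its final residue.  Kept only for
    baseline comparisons; the full 400-entry descriptor is the default.
    """
    return adjacency_matrix(segment, allow_x=allow_x).sum(axis=1)


def encode_windows(windows: list[SegmentWindow]) -> np.ndarray:
    """Stack descriptors of ``windows`` into an (n_windows, 400) array."""
    if not windows:
        return np.zeros((0, DESCRIPTOR_DIM), dtype=np.int64)
    return np.vstack([descriptor_vector(win.sequence) for win in windows])


def descriptor_table(seq: ProteinSequence, w: int = 10):
    """One row per window (id, start, end, 400 counts) as a DataFrame."""
    import pandas as pd

    windows = segment_protein(seq, w)
    rows = []
    for win in windows:
        rec = {"id": win.parent_id, "start": win.start, "end": win.end}
        vec = descriptor_vector(win.sequence)
        for (a, b), v in zip(
            ((a, b) for a in AMINO_ACIDS for b in AMINO_ACIDS), vec
        ):
            rec[f"{a}{b}"] = int(v)
        rows.append(rec)
    return pd.DataFrame(rows)
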