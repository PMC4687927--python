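"""Labeled training segments and the SOM-based train/validation split.

Annotated proteins are separated into their transmembrane and
non-transmembrane parts: each annotated membrane-embedded strand becomes one
``tm`` segment exactly as annotated, and every maximal region between
annotations is fragmented into ~10-residue ``ntm`` chunks so that the two
classes have comparable lengths.  The split into training and validation sets
is made on a self-organizing map of the 400-dim descriptors so that both sets
sample every occupied neuron — the training set keeps a complete
representation of the data space rather than holding out whole proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import AnnotatedProtein
from .encoding import SegmentWindow, descriptor_vector
from .som import SelfOrganizingMap

TM = "tm"
NTM = "ntm"

#: ntm chunk policy: cut inter-strand regions into 10-residue chunks; a final
#: remainder shorter than MIN_CHUNK is merged into the preceding chunk, so
#: chunk lengths lie in 6..15, the same band as annotated strand lengths.
CHUNK_LEN = 10
MIN_CHUNK = 6


@dataclass(frozen=True)
class LabeledSegment:
    window: SegmentWindow
    label: str  # TM or NTM

    def __post_init__(self) -> None:
        if self.label not in (TM, NTM):
            raise ValueError(f"label must be {TM!r} or {NTM!r}")

    @property
    def descriptor(self) -> np.ndarray:
        return descriptor_vector(self.window.sequence)


def _chunk_region(length: int) -> list[tuple[int, int]]:
    """Chunk offsets (0-based, half-open) for an inter-strand region."""
    if length < MIN_CHUNK:
        return []  # too short to keep and nothing to merge into
    n_full = length // CHUNK_LEN
    rem = length % CHUNK_LEN
    bounds = [(i * CHUNK_LEN, (i + 1) * CHUNK_LEN) for i in range(n_full)]
    if rem:
        if rem >= MIN_CHUNK:
            bounds.append((n_full * CHUNK_LEN, length))
        elif bounds:
            s, _ = bounds[-1]
            bounds[-1] = (s, length)  # merge short remainder into last chunk
        else:  # length in 1..5 handled above; unreachable
            return []
    return bounds


def extract_labeled_segments(protein: AnnotatedProtein) -> list[LabeledSegment]:
    """One tm segment per annotated strand + ~10-residue ntm loop chunks.

    The AnnotatedProtein invariants guarantee sorted, non-overlapping,
    in-bounds ranges.  Inter-strand regions shorter than 6 residues (tight
    hairpin turns) yield no ntm segment.
    """
    seq = protein.sequence
    out: list[LabeledSegment] = []
    boundaries = [(0, 0)] + [list(r) for r in protein.tm_regions] + [
        (seq.n + 1, seq.n + 1)
    ]
    for start, end in protein.tm_regions:
        out.append(
            LabeledSegment(
                SegmentWindow(seq.id, start, end, seq.residues[start - 1 : end]),
                TM,
            )
        )
    for (_, prev_end), (next_start, _) in zip(boundaries, boundaries[1:]):
        region_start = prev_end + 1  # first residue after previous strand
        region_end = next_start - 1
        length = region_end - region_start + 1
        for off_s, off_e in _chunk_region(max(length, 0)):
            s = region_start + off_s
            e = region_start + off_e - 1
            out.append(
                LabeledSegment(
                    SegmentWindow(seq.id, s, e, seq.residues[s - 1 : e]), NTM
                )
            )
    out.sort(key=lambda ls: ls.window.start)
    return out


@dataclass
class DatasetSplit:
    training: list[LabeledSegment]
    validation: list[LabeledSegment]
    som_shape: tuple[int, int]
    seed: int

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tstart\tend\tlabel\tset\n")
            for name, segs in (
                ("training", self.training),
                ("validation", self.validation),
            ):
                for ls in segs:
                    w = ls.window
                    fh.write(
                        f"{w.parent_id}\t{w.start}\t{w.end}\t{ls.label}\t{name}\n"
                    )


def default_som_shape(n_samples: int) -> tuple[int, int]:
    """Roughly n/10 neurons on a near-square grid."""
    side = max(2, round(math.sqrt(max(n_samples, 1) / 10.0)))
    return (side, side)


def som_split(
    segments: list[LabeledSegment],
    som_shape: tuple[int, int] | None = None,
    val_fraction: float = 0.16,
    seed: int = 0,
    epochs: int = 10,
) -> DatasetSplit:
    """Partition segments into training/validation sets via a Kohonen map.

    A SOM is trained on the segment descriptors; within each occupied neuron
    the samples are shuffled (seeded) and a share of them goes to validation,
    sized by a running quota so the overall validation fraction tracks
    ``val_fraction``, with the constraint that every neuron holding >= 2
    samples contributes at least one sample to each set.  Singleton neurons
    go entirely to training.  Fully reproducible from ``seed``.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to split")
    if som_shape is None:
        som_shape = default_som_shape(len(segments))
    if som_shape[0] * som_shape[1] < 2:
        raise ValueError("SOM shape must provide at least 2 neurons")

    X = np.vstack([ls.descriptor for ls in segments]).astype(float)
    som = SelfOrganizingMap(som_shape[0], som_shape[1], X.shape[1], seed=seed)
    som.fit(X, epochs=epochs)
    winners = som.bmu(X)

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    seen = 0
    allocated = 0
    for neuron in np.unique(winners):
        members = np.flatnonzero(winners == neuron)
        members = members[rng.permutation(len(members))]
        k = len(members)
        seen += k
        if k == 1:
            train_idx.extend(members.tolist())
            continue
        # running quota keeps the overall validation share near val_fraction
        # while every >=2-sample neuron feeds both sets
        desired = round(val_fraction * seen - allocated)
        n_val = min(max(desired, 1), k - 1)
        allocated += n_val
        val_idx.extend(members[:n_val].tolist())
        train_idx.extend(members[n_val:].tolist())

    train_idx.sort()
    val_idx.sort()
    return DatasetSplit(
        training=[segments[i] for i in train_idx],
        validation=[segments[i] for i in val_idx],
        som_shape=som_shape,
        seed=seed,
    )


def class_counts(segments: list[LabeledSegment]) -> tuple[int, int]:
    """(n_tm, n_ntm) counts."""
    n_tm = sum(1 for ls in segments if ls.label == TM)
    return n_tm, len(segments) - n_tm
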