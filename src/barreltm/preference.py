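"""Position-specific amino-acid preferences at strand boundary residues.

Candidate strand boundaries are ranked by how strongly each amino acid is
preferred at the first (N-terminal) and last (C-terminal) position of known
membrane-embedded strands.  Preferred residues score positive, disfavoured
residues negative.  The table is a first-class input (TSV) and can also be
estimated from any annotated corpus by a log-odds rule: the observed count of
residue ``a`` at strand first (last) positions against its expectation under
the corpus-wide composition, with a pseudocount, zero-centered per terminal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotations import AnnotatedProtein
from .encoding import AMINO_ACIDS


@dataclass(frozen=True)
class PreferenceTable:
    """score_N / score_C per amino acid; positive = preferred at that terminus."""

    score_n: dict[str, float]
    score_c: dict[str, float]

    def __post_init__(self) -> None:
        for name, table in (("score_N", self.score_n), ("score_C", self.score_c)):
            missing = set(AMINO_ACIDS) - set(table)
            if missing:
                raise ValueError(f"{name}: missing residues {sorted(missing)}")
            bad = [a for a, v in table.items() if not np.isfinite(v)]
            if bad:
                raise ValueError(f"{name}: non-finite scores for {bad}")

    def segment_score(self, first_residue: str, last_residue: str) -> float:
        """Boundary score of a candidate: score_N(first) + score_C(last)."""
        try:
            return self.score_n[first_residue] + self.score_c[last_residue]
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]!r} not in preference table")

    @classmethod
    def zeros(cls) -> "PreferenceTable":
        z = {a: 0.0 for a in AMINO_ACIDS}
        return cls(dict(z), dict(z))


def estimate_preference_table(
    proteins: list[AnnotatedProtein], pseudocount: float = 1.0
) -> PreferenceTable:
    """Log-odds preference scores from an annotated corpus.

    For each terminal position, score(a) = log2[(count_a + pc) /
    (expected_a + pc)] where expected_a = (number of strands) x (corpus-wide
    frequency of a), then zero-centered across the 20 amino acids.
    Deterministic and invariant to protein order.
    """
    if not any(p.tm_regions for p in proteins):
        raise ValueError("no annotated transmembrane regions in corpus")
    comp = np.zeros(20)
    first = np.zeros(20)
    last = np.zeros(20)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    n_strands = 0
    for p in proteins:
        for ch in p.sequence.residues:
            comp[aa_index[ch]] += 1
        for start, end in p.tm_regions:
            first[aa_index[p.sequence.residues[start - 1]]] += 1
            last[aa_index[p.sequence.residues[end - 1]]] += 1
            n_strands += 1
    freq = comp / comp.sum()

    def scores(counts: np.ndarray) -> dict[str, float]:
        expected = n_strands * freq
        raw = np.log2((counts + pseudocount) / (expected + pseudocount))
        raw = raw - raw.mean()
        return {a: float(v) for a, v in zip(AMINO_ACIDS, raw)}

    return PreferenceTable(scores(first), scores(last))


def default_table() -> PreferenceTable:
    """The shipped default table, estimated from a synthetic barrel corpus.

    Clearly non-canonical (see the file header): it exists so the predictor
    works out of the box and for demos; estimate or supply a corpus-specific
    table for real sequences.
    """
    return load_table(Path(__file__).parent / "data" / "default_preference.tsv")


def save_table(table: PreferenceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("amino_acid\tscore_N\tscore_C\n")
        for a in AMINO_ACIDS:
            fh.write(f"{a}\t{table.score_n[a]:.6f}\t{table.score_c[a]:.6f}\n")


def load_table(path: str | Path) -> PreferenceTable:
    """Read a preference TSV; '#' comment lines ignored; all 20 rows required."""
    score_n: dict[str, float] = {}
    score_c: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "amino_acid":
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            aa = parts[0].strip()
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{path}: line {lineno}: unknown residue {aa!r}")
            if aa in score_n:
                raise ValueError(f"{path}: line {lineno}: duplicate row for {aa}")
            try:
                score_n[aa] = float(parts[1])
                score_c[aa] = float(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric score for {aa}"
                ) from exc
    missing = sorted(set(AMINO_ACIDS) - set(score_n))
    if missing:
        raise ValueError(f"{path}: missing rows for {missing}")
    return PreferenceTable(score_n, score_c)
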