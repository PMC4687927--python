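"""Annotated proteins and the plain-text region/FASTA formats.

All coordinates in the TSV dialect are 1-based inclusive; the optional BED
export is 0-based half-open (start0 = start - 1, end0 = end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoding import ProteinSequence

REGION_HEADER = ("protein_id", "start", "end")


@dataclass(frozen=True)
class AnnotatedProtein:
    """A protein sequence plus ground-truth transmembrane residue ranges.

    Ranges are 1-based inclusive, sorted, non-overlapping, each at least two
    residues long, and fall within the sequence.
    """

    sequence: ProteinSequence
    tm_regions: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        n = self.sequence.n
        regions = tuple(sorted(tuple(r) for r in self.tm_regions))
        object.__setattr__(self, "tm_regions", regions)
        prev_end = 0
        for start, end in regions:
            if not (1 <= start <= end <= n):
                raise ValueError(
                    f"protein {self.sequence.id!r}: region {start}..{end} "
                    f"outside sequence of {n} residues"
                )
            if end - start + 1 < 2:
                raise ValueError(
                    f"protein {self.sequence.id!r}: region {start}..{end} "
                    "shorter than 2 residues"
                )
            if start <= prev_end:
                raise ValueError(
                    f"protein {self.sequence.id!r}: overlapping regions "
                    f"at {start}..{end}"
                )
            prev_end = end

    @property
    def id(self) -> str:
        return self.sequence.id


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (multi-record) FASTA; description after the first token ignored."""
    return [
        ProteinSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(proteins: list[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.residues), id=p.id, description="") for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_regions(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a region TSV (protein_id, start, end; 1-based inclusive).

    A header line matching the documented column names is accepted and
    skipped; lines starting with '#' are ignored.
    """
    regions: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if tuple(p.strip() for p in parts[:3]) == REGION_HEADER:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            pid, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            regions.setdefault(pid, []).append((start, end))
    for pid in regions:
        regions[pid].sort()
    return regions


def write_regions(
    regions: dict[str, list[tuple[int, int]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REGION_HEADER) + "\n")
        for pid in regions:
            for start, end in regions[pid]:
                fh.write(f"{pid}\t{start}\t{end}\n")


def regions_to_bed(
    regions: dict[str, list[tuple[int, int]]], path: str | Path
) -> None:
    """Export regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for pid in regions:
            for start, end in regions[pid]:
                fh.write(f"{pid}\t{start - 1}\t{end}\n")


def regions_from_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file back into 1-based inclusive ranges."""
    regions: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            pid, start0, end0 = line.split("\t")[:3]
            regions.setdefault(pid, []).append((int(start0) + 1, int(end0)))
    for pid in regions:
        regions[pid].sort()
    return regions


def load_annotated(
    fasta_path: str | Path, regions_path: str | Path
) -> list[AnnotatedProtein]:
    """Pair a FASTA with a region TSV into annotated proteins.

    Every protein in the FASTA must have at least one annotated region.
    """
    proteins = read_fasta(fasta_path)
    regions = read_regions(regions_path)
    missing = [p.id for p in proteins if p.id not in regions]
    if missing:
        raise ValueError(
            "proteins without annotations in "
            f"{regions_path}: {', '.join(missing)}"
        )
    return [
        AnnotatedProtein(p, tuple(regions[p.id])) for p in proteins
    ]
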