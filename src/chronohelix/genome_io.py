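"""Genome FASTA/GFF ingestion and coding / non-coding partitioning.

The analyses downstream only need a coarse two-class segmentation of each
sequence: the union of annotated CDS intervals ("coding") and its complement
("non-coding").  Coordinates are converted from GFF's 1-based inclusive
convention to 0-based half-open slices immediately on read and stay that way
everywhere else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

VALID_ALPHABET = frozenset("ACGTN")

RegionKind = Literal["coding", "noncoding"]


@dataclass(frozen=True)
class GenomeRecord:
    """A single sequence with identifier, alphabet-checked and uppercased."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Region:
    """Half-open interval [start, end) of one class, with its sequence."""

    seq_id: str
    start: int
    end: int
    kind: RegionKind
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"region [{self.start}, {self.end}): length "
                f"{self.end - self.start} != sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionPartition:
    """Ordered, disjoint regions exactly covering the source sequence."""

    regions: list[Region]
    source: GenomeRecord = field(repr=False)

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("partition must contain at least one region")
        pos = 0
        for r in self.regions:
            if r.start != pos:
                raise ValueError(
                    f"partition gap/overlap at {pos}: next region starts at {r.start}"
                )
            pos = r.end
        if pos != len(self.source):
            raise ValueError(
                f"partition covers [0, {pos}) but source has length {len(self.source)}"
            )

    def by_kind(self, kind: RegionKind) -> list[Region]:
        return [r for r in self.regions if r.kind == kind]

    def stats(self) -> dict[str, float]:
        coding = sum(len(r) for r in self.by_kind("coding"))
        noncoding = sum(len(r) for r in self.by_kind("noncoding"))
        return {
            "coding_bp": coding,
            "noncoding_bp": noncoding,
            "noncoding_fraction": noncoding_fraction(coding, noncoding),
        }


def noncoding_fraction(coding_bp: int, noncoding_bp: int) -> float:
    """Non-coding share of the genome, as a fraction of total bases."""
    total = coding_bp + noncoding_bp
    if total <= 0:
        raise ValueError("empty genome")
    return noncoding_bp / total


def read_fasta(path: str | Path, on_illegal: str = "reject") -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Parameters
    ----------
    path:
        FASTA file path.
    on_illegal:
        ``"reject"`` raises on any letter outside ``ACGTN``; ``"mask"``
        silently maps such letters to ``N``.
    """
    if on_illegal not in ("reject", "mask"):
        raise ValueError("on_illegal must be 'reject' or 'mask'")
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_ALPHABET
        if bad:
            if on_illegal == "reject":
                offender = sorted(bad)[0]
                raise ValueError(
                    f"record {rec.id!r}: illegal character {offender!r} "
                    f"at position {seq.index(offender)}"
                )
            seq = "".join(c if c in VALID_ALPHABET else "N" for c in seq)
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_gff(
    path: str | Path, feature_type: str = "CDS"
) -> list[tuple[str, int, int, str]]:
    """Read features of one type from a GFF3 file.

    Returns ``(seq_id, start_1based, end_1based, strand)`` tuples with the
    1-based inclusive coordinates preserved exactly as read.
    """
    features: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected >=8 tab-separated columns")
            seq_id, _source, ftype, start_s, end_s, _score, strand = fields[:7]
            if ftype != feature_type:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end {end} < start {start}")
            features.append((seq_id, start, end, strand))
    return features


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def partition_regions(
    genome: GenomeRecord,
    features: Sequence[tuple[str, int, int, str]],
    merge_overlaps: bool = True,
) -> RegionPartition:
    """Split a genome into alternating coding / non-coding regions.

    ``features`` carry 1-based inclusive coordinates (as from
    :func:`read_gff`); coding intervals are the strand-insensitive union of
    features referring to ``genome.id``, and non-coding regions are the
    complement.
    """
    n = len(genome)
    raw: list[tuple[int, int]] = []
    for seq_id, start1, end1, _strand in features:
        if seq_id != genome.id:
            continue
        start0, end0 = start1 - 1, end1
        if start0 < 0 or end0 > n:
            raise ValueError(
                f"feature ({start1}, {end1}) exceeds sequence bounds [1, {n}]"
            )
        raw.append((start0, end0))
    if not merge_overlaps and raw:
        merged_check = _merge_intervals(raw)
        if len(merged_check) != len(raw):
            raise ValueError("overlapping features with merge_overlaps=False")
    coding = _merge_intervals(raw)

    regions: list[Region] = []

    def add(start: int, end: int, kind: RegionKind) -> None:
        regions.append(
            Region(genome.id, start, end, kind, genome.sequence[start:end])
        )

    pos = 0
    for start, end in coding:
        if start > pos:
            add(pos, start, "noncoding")
        add(start, end, "coding")
        pos = end
    if pos < n:
        add(pos, n, "noncoding")
    return RegionPartition(regions=regions, source=genome)


def extract_window(
    partition: RegionPartition, nc_len: int, c_len: int
) -> tuple[str, str]:
    """First contiguous non-coding and coding stretches of the given lengths.

    Mirrors the analysis-window convention used by the tunneling experiments:
    a non-coding segment followed by a coding segment, taken from the first
    regions long enough to supply them.
    """

    def first_stretch(kind: RegionKind, length: int) -> str:
        if length == 0:
            return ""
        for region in partition.by_kind(kind):
            if len(region) >= length:
                return region.sequence[:length]
        raise ValueError(
            f"no contiguous {kind} stretch of length {length} in partition"
        )

    return first_stretch("noncoding", nc_len), first_stretch("coding", c_len)


def write_bed(partition: RegionPartition, path: str | Path) -> None:
    """Write the partition as BED (0-based half-open, name = region kind)."""
    with open(path, "w") as fh:
        for r in partition.regions:
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.kind}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read intervals written by :func:`write_bed`."""
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            seq_id, start, end, name = line.split()[:4]
            out.append((seq_id, int(start), int(end), name))
    return out
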