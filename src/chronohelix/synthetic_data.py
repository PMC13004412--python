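"""Synthetic annotated genomes for download-free testing of every stage.

The generator emulates the gross features the pipeline is sensitive to:

* a GC-rich genome (default 65% GC) with a large coding fraction (default
  91%), laid out as alternating non-coding / coding blocks;
* codon-position-dependent base composition in coding blocks, controlled by
  ``codon_bias_strength``: position-specific G/C and A/T asymmetries are
  applied on top of the genome-wide GC target, which keeps GC content intact
  while skewing the compositional balance.  Skewing lowers the coding
  regions' compositional Shannon entropy below the i.i.d. non-coding
  baseline, so the designed direction of the class difference in this
  synthetic model is coding < non-coding; at strength 0 the construction is
  an exact null (both classes i.i.d. from the same distribution);
* a "control" construction that falsely splits a single non-coding stretch
  into pseudo-non-coding and pseudo-coding halves;
* composition-preserving sequence shuffles.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .genome_io import GenomeRecord, Region, RegionPartition, partition_regions

_BASES = np.array(list("ACGT"))

# Per-codon-position skew directions (G vs C, A vs T), applied at full
# strength as a fractional reallocation within each GC class.  Loosely mimics
# the purine-rich first position and wobble G preference of bacterial genes;
# at strength 1 the aggregate coding entropy sits ~0.09 bits below the
# symmetric non-coding baseline, the magnitude of a typical class gap.
_POSITION_SKEWS = (
    (+0.90, +0.54),   # pos 1: G over C, A over T
    (-0.54, +0.90),   # pos 2: C over G, A over T
    (+0.90, -0.90),   # pos 3: G over C, T over A
)


@dataclass(frozen=True)
class SynthGenomeConfig:
    length: int = 500_000
    gc_content: float = 0.65
    coding_fraction: float = 0.91
    n_regions: int = 20
    codon_bias_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0 < self.coding_fraction < 1:
            raise ValueError("coding_fraction must be in (0, 1)")
        if self.codon_bias_strength < 0:
            raise ValueError("codon_bias_strength must be >= 0")
        if self.n_regions < 1:
            raise ValueError("need at least one coding region")
        # Each coding block needs >= 3 bp and each of the n+1 non-coding
        # gaps >= 1 bp for the partition to be feasible.
        if self.length * self.coding_fraction < 3 * self.n_regions:
            raise ValueError("coding fraction/length too small for n_regions")
        if self.length * (1 - self.coding_fraction) < self.n_regions + 1:
            raise ValueError("non-coding budget too small for n_regions gaps")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _codon_position_probs(gc: float, strength: float) -> list[np.ndarray]:
    """Per-codon-position base probabilities at the given bias strength.

    The skew reallocates probability within the GC pair and within the AT
    pair, so each position (and hence the aggregate) keeps GC = gc exactly.
    """
    w = min(strength, 1.0)
    probs = []
    for skew_gc, skew_at in _POSITION_SKEWS:
        p_at, p_gc = (1 - gc) / 2, gc / 2
        d_gc = w * skew_gc * p_gc
        d_at = w * skew_at * p_at
        probs.append(
            np.array([p_at + d_at, p_gc - d_gc, p_gc + d_gc, p_at - d_at])
        )
    return probs


def _draw(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=n, p=probs)


def generate_genome(
    config: SynthGenomeConfig,
    fasta_path: Optional[str | Path] = None,
    gff_path: Optional[str | Path] = None,
    seq_id: str = "synth1",
) -> tuple[GenomeRecord, list[tuple[str, int, int, str]], RegionPartition]:
    """Generate an annotated synthetic genome.

    Returns the genome record, the CDS feature list (1-based inclusive, as a
    GFF reader would produce), and the resulting partition.  Optionally
    writes FASTA and GFF3 files.
    """
    rng = np.random.default_rng(config.seed)
    n = config.length
    n_coding_total = int(round(n * config.coding_fraction))
    n_blocks = config.n_regions

    # Split the coding budget into n blocks and the non-coding budget into
    # n+1 gaps, all as even as feasibility allows.
    coding_lens = np.full(n_blocks, n_coding_total // n_blocks)
    coding_lens[: n_coding_total % n_blocks] += 1
    n_nc_total = n - n_coding_total
    nc_lens = np.full(n_blocks + 1, n_nc_total // (n_blocks + 1))
    nc_lens[: n_nc_total % (n_blocks + 1)] += 1

    nc_probs = _base_probs(config.gc_content)
    pos_probs = _codon_position_probs(config.gc_content, config.codon_bias_strength)

    codes = np.empty(n, dtype=np.int64)
    features: list[tuple[str, int, int, str]] = []
    pos = 0
    for block in range(n_blocks):
        gap = int(nc_lens[block])
        if gap:
            codes[pos : pos + gap] = _draw(rng, gap, nc_probs)
            pos += gap
        clen = int(coding_lens[block])
        start0 = pos
        for frame in range(3):
            idx = np.arange(pos + frame, pos + clen, 3)
            codes[idx] = _draw(rng, len(idx), pos_probs[frame])
        pos += clen
        features.append((seq_id, start0 + 1, pos, "+"))
    gap = int(nc_lens[-1])
    if gap:
        codes[pos : pos + gap] = _draw(rng, gap, nc_probs)
        pos += gap
    assert pos == n

    sequence = "".join(_BASES[codes])
    genome = GenomeRecord(id=seq_id, sequence=sequence)
    partition = partition_regions(genome, features)

    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            fh.write(f">{seq_id}\n")
            for i in range(0, n, 80):
                fh.write(sequence[i : i + 80] + "\n")
    if gff_path is not None:
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for sid, s1, e1, strand in features:
                fh.write(
                    f"{sid}\tchronohelix\tCDS\t{s1}\t{e1}\t.\t{strand}\t0\t"
                    f"ID=cds{s1}\n"
                )
    return genome, features, partition


def make_control(
    partition: RegionPartition, nc_len: int, c_len: int
) -> tuple[str, str]:
    """Falsely split one non-coding stretch into pseudo-region halves.

    Returns (pseudo_noncoding, pseudo_coding): the first nc_len bases and the
    following c_len bases of the first non-coding region long enough to
    supply both.  Both halves are genuinely non-coding sequence.
    """
    needed = nc_len + c_len
    for region in partition.by_kind("noncoding"):
        if len(region) >= needed:
            return region.sequence[:nc_len], region.sequence[nc_len:needed]
    raise ValueError(
        f"no contiguous non-coding stretch of length {needed} in partition"
    )


def shuffle_sequence(sequence: str, seed: int) -> str:
    """Uniform random permutation of the characters (composition preserved)."""
    if not sequence:
        raise ValueError("cannot shuffle an empty sequence")
    arr = np.array(list(sequence))
    np.random.default_rng(seed).shuffle(arr)
    return "".join(arr)
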