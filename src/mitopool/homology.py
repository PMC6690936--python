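"""Sliding-window exact homology between two mitochondrial genomes.

A position of genome B is flagged as homologous when it lies inside at least
one length-``window`` substring of B that occurs exactly, on the same strand,
somewhere in genome A. The default window of 19 matches the minimal seed
length of the BWA-MEM aligner, so flagged regions are exactly those where a
seed from one genome can land on the other and produce cross-mapping reads.
Reverse-complement matches can be enabled but are off by default.

Read-level uniqueness between two alignments of the same read set is
summarized by :func:`classify_shared_reads`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .readmodel import SampleAlignment

__all__ = ["HomologyMask", "UniquenessCounts", "homology_mask", "classify_shared_reads", "mask_to_bed", "write_bed"]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HomologyMask:
    """Boolean flag per position of genome B (True = homologous to A)."""

    flags: np.ndarray  # bool per position of genome B
    window: int

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


@dataclass(frozen=True)
class UniquenessCounts:
    unique_a: int
    unique_b: int
    shared: int

    @property
    def total(self) -> int:
        return self.unique_a + self.unique_b + self.shared

    @property
    def ratio(self) -> float:
        """unique_a / unique_b; inf when nothing is unique to B."""
        if self.unique_b == 0:
            logger.info("uniqueness ratio undefined (unique_b = 0); reporting inf")
            return math.inf
        return self.unique_a / self.unique_b


def homology_mask(genome_a: str, genome_b: str, window: int = 19) -> HomologyMask:
    """Flag every position of ``genome_b`` covered by a window-mer of B that
    occurs exactly in ``genome_a``.

    Matching is forward-strand only; use
    :func:`homology_mask_revcomp_aware` to also match reverse-complement
    windows. Windows never wrap the circular origin.
    """
    return _homology_mask(genome_a, genome_b, window, include_revcomp=False)


def _homology_mask(
    genome_a: str, genome_b: str, window: int, *, include_revcomp: bool
) -> HomologyMask:
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > min(len(genome_a), len(genome_b)):
        raise ValueError("window exceeds a genome length")
    genome_a = genome_a.upper()
    genome_b = genome_b.upper()
    kmers = {genome_a[i : i + window] for i in range(len(genome_a) - window + 1)}
    if include_revcomp:
        kmers |= {_revcomp(k) for k in kmers}
    flags = np.zeros(len(genome_b), dtype=bool)
    for i in range(len(genome_b) - window + 1):
        if genome_b[i : i + window] in kmers:
            flags[i : i + window] = True
    return HomologyMask(flags=flags, window=window)


def homology_mask_revcomp_aware(genome_a: str, genome_b: str, window: int = 19) -> HomologyMask:
    """Like :func:`homology_mask` but also matching reverse-complement windows."""
    return _homology_mask(genome_a, genome_b, window, include_revcomp=True)


def classify_shared_reads(
    sam_vs_a: SampleAlignment, sam_vs_b: SampleAlignment
) -> UniquenessCounts:
    """Partition a read set by where it aligned: only to A, only to B, or both.

    Both alignments must come from the same read set (shared read_id
    namespace); the counts then sum to the number of distinct read ids seen.
    """
    ids_a = {frag.read_id for frag in sam_vs_a.fragments}
    ids_b = {frag.read_id for frag in sam_vs_b.fragments}
    shared = ids_a & ids_b
    return UniquenessCounts(
        unique_a=len(ids_a - shared),
        unique_b=len(ids_b - shared),
        shared=len(shared),
    )


def mask_to_bed(mask: HomologyMask, chrom: str = "genome_b") -> list[tuple[str, int, int]]:
    """Flagged runs as BED intervals (0-based, half-open)."""
    flags = mask.flags
    intervals: list[tuple[str, int, int]] = []
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, end in zip(edges[::2], edges[1::2]):
        intervals.append((chrom, int(start), int(end)))
    return intervals


def write_bed(mask: HomologyMask, path: str | Path, chrom: str = "genome_b") -> None:
    lines = [f"{c}\t{s}\t{e}" for c, s, e in mask_to_bed(mask, chrom)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
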