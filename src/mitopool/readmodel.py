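"""SAM ingestion, per-read observations, coverage and sample pooling.

Reads aligned to a mitochondrial reference are reduced to per-read
``(position, base, error_prob)`` observations, the only information the
mixture model needs. Error probabilities come from Phred qualities
(``eps = 10**(-Q/10)``). Pileups and mean coverage support the study's
sample-retention rule (mean coverage of at least 10 over the full genome)
and treatment-plant pooling.

Secondary and supplementary alignments are skipped so a read is never
counted twice; duplicate marking is not performed (a hook point would sit in
:func:`read_sam`'s record filter). The genome is treated as linear in SAM
coordinates; origin-spanning reads are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

__all__ = [
    "AlignedFragment",
    "SampleAlignment",
    "CoverageProfile",
    "read_sam",
    "coverage_profile",
    "filter_by_coverage",
    "pool_samples",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedFragment:
    """One aligned read: parallel arrays of reference positions (1-based),
    observed bases and per-base error probabilities."""

    read_id: str
    positions: np.ndarray  # int64, strictly increasing, 1-based
    bases: np.ndarray  # '<U1' over A/C/G/T/N
    error_probs: np.ndarray  # float64 in (0, 1]

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.bases) == len(self.error_probs)):
            raise ValueError("observation arrays must have equal length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"read {self.read_id!r}: positions not strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SampleAlignment:
    """All aligned fragments of one (possibly pooled) sample."""

    sample_id: str
    reference_id: str
    genome_length: int
    fragments: tuple[AlignedFragment, ...] = field(default=())

    def __post_init__(self) -> None:
        for frag in self.fragments:
            if len(frag) and frag.positions[-1] > self.genome_length:
                raise ValueError(
                    f"read {frag.read_id!r} extends past genome length "
                    f"{self.genome_length}"
                )

    @property
    def n_reads(self) -> int:
        return len(self.fragments)


@dataclass(frozen=True)
class CoverageProfile:
    depth: np.ndarray  # int64 per reference position

    @property
    def mean(self) -> float:
        return float(self.depth.sum() / len(self.depth))


def read_sam(path: str | Path, reference_id: str, genome_length: int) -> SampleAlignment:
    """Parse a SAM file into per-read observations.

    Keeps primary, mapped records aligned to ``reference_id``. The CIGAR is
    walked via pysam's aligned pairs: M/=/X consume read and reference, I
    consumes the read only (inserted bases dropped), D/N consume the
    reference only (those positions stay uncovered), S/H never touch the
    reference. The sample id is the file stem.
    """
    path = Path(path)
    fragments: list[AlignedFragment] = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.reference_name != reference_id:
                    continue
                seq = rec.query_sequence
                quals = rec.query_qualities
                if seq is None or quals is None:
                    raise ValueError(
                        f"{path}: record {rec.query_name!r} lacks SEQ or QUAL"
                    )
                pairs = rec.get_aligned_pairs(matches_only=True)
                if not pairs:
                    continue
                qidx = np.fromiter((q for q, _ in pairs), dtype=np.int64)
                rpos = np.fromiter((r for _, r in pairs), dtype=np.int64) + 1
                bases = np.frombuffer(seq.upper().encode(), dtype="S1")[qidx].astype("U1")
                qarr = np.asarray(quals, dtype=np.float64)[qidx]
                eps = np.power(10.0, -qarr / 10.0)
                fragments.append(AlignedFragment(rec.query_name, rpos, bases, eps))
    except (ValueError, OSError) as exc:
        # pysam reports text-SAM parse failures as ValueError or OSError
        raise ValueError(f"malformed SAM in {path}: {exc}") from exc
    return SampleAlignment(
        sample_id=path.stem,
        reference_id=reference_id,
        genome_length=genome_length,
        fragments=tuple(fragments),
    )


def coverage_profile(sample: SampleAlignment) -> CoverageProfile:
    """Per-position read depth; the mean is taken over every genome position,
    zero-depth ones included."""
    depth = np.zeros(sample.genome_length, dtype=np.int64)
    for frag in sample.fragments:
        np.add.at(depth, frag.positions - 1, 1)
    return CoverageProfile(depth=depth)


def filter_by_coverage(
    samples: Sequence[SampleAlignment], min_mean: float = 10.0
) -> list[SampleAlignment]:
    """Keep samples whose mean coverage is >= ``min_mean`` (inclusive bound),
    preserving order; each decision is logged."""
    kept: list[SampleAlignment] = []
    for sample in samples:
        mean = coverage_profile(sample).mean
        passed = mean >= min_mean
        logger.info(
            "coverage filter: sample=%s mean=%.4f threshold=%.4f -> %s",
            sample.sample_id,
            mean,
            min_mean,
            "retained" if passed else "excluded",
        )
        if passed:
            kept.append(sample)
    return kept


def pool_samples(samples: Sequence[SampleAlignment], pooled_id: str) -> SampleAlignment:
    """Merge samples from one treatment plant into a single alignment.

    Fragments are unioned as a multiset; read ids are prefixed with their
    sample of origin so pooling never collapses two reads. The pooled mean
    coverage is exactly the sum of the member means.
    """
    if not samples:
        raise ValueError("cannot pool an empty sample list")
    ref_ids = {s.reference_id for s in samples}
    lengths = {s.genome_length for s in samples}
    if len(ref_ids) > 1 or len(lengths) > 1:
        raise ValueError(
            f"cannot pool samples against different references: {sorted(ref_ids)}"
        )
    fragments: list[AlignedFragment] = []
    for sample in samples:
        for frag in sample.fragments:
            fragments.append(
                AlignedFragment(
                    read_id=f"{sample.sample_id}:{frag.read_id}",
                    positions=frag.positions,
                    bases=frag.bases,
                    error_probs=frag.error_probs,
                )
            )
    return SampleAlignment(
        sample_id=pooled_id,
        reference_id=samples[0].reference_id,
        genome_length=samples[0].genome_length,
        fragments=tuple(fragments),
    )
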