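"""Synthetic data: toy phylogenies, pooled mixture reads, contaminant genomes.

The generator emulates the data a pooled (sewage-style) sample presents to
the pipeline: a set of haplotypes defined by private substitutions on a toy
reference, single-end 150 bp reads drawn from a haplotype mixture at set
proportions with independent per-base substitution errors at a fixed rate
(quality string uniform, matching that rate), and a diverged contaminant
genome that shares exact sequence windows with the target reference.

Reads never span the circular origin, carry no indels, and have a single
quality value per run — deliberate simplifications that keep every truth
quantity analytic. Every emitted read's origin haplotype is recorded in a
:class:`SimulationTruth` so estimates can be scored against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .phylotree import HaplotypeDefinition, PhyloTreeDB, Variant, haplotype_sequence

__all__ = [
    "SimulationTruth",
    "simulate_phylotree",
    "simulate_mixture_reads",
    "simulate_contaminant",
    "write_fasta",
    "read_fasta",
]

_BASES = np.array(list("ACGT"))

# Phred cap for error_rate -> quality: a zero error rate has no finite Phred
# score, so qualities are capped at Q=60 (eps = 1e-6), keeping error
# probabilities strictly positive as the read model requires.
_MAX_QUALITY = 60


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated read set."""

    proportions: Mapping[str, float]
    read_origins: Mapping[str, str]  # read_id -> haplotype name
    error_rate: float
    coverage: float
    seed: int

    def origin_fractions(self) -> dict[str, float]:
        """Empirical fraction of reads drawn from each haplotype."""
        total = len(self.read_origins)
        counts: dict[str, int] = {}
        for origin in self.read_origins.values():
            counts[origin] = counts.get(origin, 0) + 1
        return {name: counts.get(name, 0) / total for name in self.proportions}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "proportions": dict(self.proportions),
                    "read_origins": dict(self.read_origins),
                    "error_rate": self.error_rate,
                    "coverage": self.coverage,
                    "seed": self.seed,
                },
                indent=2,
            ),
            encoding="utf-8",
        )


def simulate_phylotree(
    n_haplotypes: int,
    variants_per_haplotype: int,
    genome_length: int,
    seed: int,
    *,
    reference_id: str = "synthetic_ref",
) -> tuple[str, PhyloTreeDB]:
    """Random reference plus haplotypes with private defining substitutions.

    Every haplotype receives ``variants_per_haplotype`` substitutions at
    globally distinct positions, so any two haplotype sequences differ at
    exactly ``2 * variants_per_haplotype`` sites and the mixture is fully
    identifiable. Haplotypes are named ``S1a, S2a, ...`` with haplogroup
    labels ``S1, S2, ...`` (prefix rollup groups each haplotype alone).
    """
    needed = n_haplotypes * variants_per_haplotype
    if needed > genome_length:
        raise ValueError(
            f"{n_haplotypes} haplotypes x {variants_per_haplotype} private variants "
            f"need {needed} distinct positions but the genome has {genome_length}"
        )
    rng = np.random.default_rng(seed)
    reference = "".join(rng.choice(_BASES, size=genome_length))
    positions = rng.choice(genome_length, size=needed, replace=False) + 1  # 1-based
    haplotypes: dict[str, HaplotypeDefinition] = {}
    labels: list[str] = []
    for i in range(n_haplotypes):
        label = f"S{i + 1}"
        name = f"{label}a"
        labels.append(label)
        variants = []
        for p in positions[i * variants_per_haplotype : (i + 1) * variants_per_haplotype]:
            ref_base = reference[p - 1]
            alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
            variants.append(Variant(int(p), ref_base, str(alt_base)))
        haplotypes[name] = HaplotypeDefinition(name, tuple(variants))
    db = PhyloTreeDB(
        reference_id=reference_id,
        genome_length=genome_length,
        haplotypes=haplotypes,
        haplogroup_labels=tuple(labels),
    )
    return reference, db


def _error_rate_to_quality(error_rate: float) -> int:
    if error_rate <= 0:
        return _MAX_QUALITY
    return min(_MAX_QUALITY, round(-10.0 * math.log10(error_rate)))


def simulate_mixture_reads(
    reference: str,
    db: PhyloTreeDB,
    proportions: Sequence[float] | Mapping[str, float],
    coverage: float,
    *,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    sample_id: str = "sim",
    out_sam: str | Path | None = None,
    out_fastq: str | Path | None = None,
) -> tuple[str | None, str | None, SimulationTruth]:
    """Draw pooled single-end reads from a haplotype mixture.

    The read count is ``round(coverage * genome_length / read_length)``. Each
    read's origin haplotype follows ``proportions`` (over ``db`` haplotypes,
    in database order when given as a sequence), its start is uniform over
    positions where the read fits without wrapping the origin, its bases copy
    the origin haplotype's sequence, and each base is independently replaced
    by a uniform different base with probability ``error_rate``. The quality
    string is uniform at the Phred score matching ``error_rate``. SAM records
    carry the true positions, so an aligner is unnecessary.

    Returns the SAM and FASTQ paths (``None`` when not requested) and the
    :class:`SimulationTruth`.
    """
    names = db.names
    if isinstance(proportions, Mapping):
        props = np.array([float(proportions.get(n, 0.0)) for n in names])
    else:
        if len(proportions) != len(names):
            raise ValueError("proportions length disagrees with the database")
        props = np.asarray(proportions, dtype=np.float64)
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must be non-negative and sum to 1")
    genome_length = db.genome_length
    if read_length > genome_length:
        raise ValueError("read_length exceeds the genome length")
    rng = np.random.default_rng(seed)
    n_reads = round(coverage * genome_length / read_length)
    sequences = {
        name: np.frombuffer(haplotype_sequence(db, reference, name).encode(), dtype="S1")
        for name in names
    }
    origins = rng.choice(len(names), size=n_reads, p=props / props.sum())
    starts = rng.integers(1, genome_length - read_length + 2, size=n_reads)  # 1-based
    quality = _error_rate_to_quality(error_rate)
    qual_string = chr(quality + 33) * read_length
    read_origins: dict[str, str] = {}
    sam_lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{db.reference_id}\tLN:{genome_length}",
        f"@PG\tID:mitopool-sim\tPN:mitopool-sim\tCL:seed={seed}",
    ]
    fastq_lines: list[str] = []
    for i in range(n_reads):
        name = names[origins[i]]
        start = int(starts[i])
        read_id = f"{sample_id}_read{i:06d}"
        read_origins[read_id] = name
        bases = sequences[name][start - 1 : start - 1 + read_length].astype("U1")
        if error_rate > 0:
            err = rng.random(read_length) < error_rate
            for j in np.flatnonzero(err):
                bases[j] = rng.choice([b for b in "ACGT" if b != bases[j]])
        seq = "".join(bases)
        sam_lines.append(
            f"{read_id}\t0\t{db.reference_id}\t{start}\t60\t{read_length}M\t*\t0\t0\t"
            f"{seq}\t{qual_string}"
        )
        fastq_lines.append(f"@{read_id}\n{seq}\n+\n{qual_string}")
    truth = SimulationTruth(
        proportions={n: float(p) for n, p in zip(names, props)},
        read_origins=read_origins,
        error_rate=error_rate,
        coverage=coverage,
        seed=seed,
    )
    sam_path = fastq_path = None
    if out_sam is not None:
        sam_path = str(out_sam)
        Path(sam_path).write_text("\n".join(sam_lines) + "\n", encoding="utf-8")
    if out_fastq is not None:
        fastq_path = str(out_fastq)
        Path(fastq_path).write_text("\n".join(fastq_lines) + "\n", encoding="utf-8")
    return sam_path, fastq_path, truth


def simulate_contaminant(
    reference: str,
    divergence: float,
    preserved_windows: Sequence[tuple[int, int]],
    seed: int,
    *,
    homology_window: int = 19,
    max_retries: int = 50,
) -> str:
    """A diverged copy of the reference sharing exact preserved windows.

    Outside the preserved windows (1-based ``(start, length)`` pairs,
    non-overlapping) each base is independently substituted with probability
    ``divergence``; inside them the sequence is untouched. Candidates where
    any stray length-``homology_window`` substring still matches the
    reference outside the preserved windows are rejected and resampled, so
    the homology mask of the result is exactly the union of preserved windows
    of length >= ``homology_window``.
    """
    if not 0 < divergence <= 1:
        raise ValueError("divergence must be in (0, 1]")
    genome_length = len(reference)
    preserved = np.zeros(genome_length, dtype=bool)
    spans = sorted((int(s), int(s) + int(l) - 1) for s, l in preserved_windows)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError("preserved windows overlap")
    for start, end in spans:
        if start < 1 or end > genome_length:
            raise ValueError(f"preserved window ({start}, {end}) out of bounds")
        preserved[start - 1 : end] = True
    expected = np.zeros(genome_length, dtype=bool)
    for start, end in spans:
        if end - start + 1 >= homology_window:
            expected[start - 1 : end] = True

    from .homology import homology_mask  # local import: avoids cycle at module load

    ref_arr = np.frombuffer(reference.encode(), dtype="S1").astype("U1")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        out = ref_arr.copy()
        mutate = (rng.random(genome_length) < divergence) & ~preserved
        for j in np.flatnonzero(mutate):
            out[j] = rng.choice([b for b in "ACGT" if b != out[j]])
        candidate = "".join(out)
        mask = homology_mask(reference, candidate, homology_window)
        if np.array_equal(mask.flags, expected):
            return candidate
    raise RuntimeError(
        "could not generate a contaminant whose homology is confined to the "
        "preserved windows; try a higher divergence"
    )


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    """Write sequences as plain-text FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
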