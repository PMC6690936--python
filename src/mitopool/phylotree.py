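"""Haplotype-definition databases and haplogroup mapping.

A haplotype is defined here, PhyloTree-style, by a named set of single-base
substitutions relative to a mitochondrial reference sequence (rCRS for real
data). Databases are read from a simple TSV or JSON dialect; each haplotype
may be rolled up to a coarser haplogroup label via longest-prefix matching
against a user-supplied label list.

Only substitutions are supported: insertions, deletions and back-mutation
notation are rejected at load time with a clear message, because the
downstream read-consistency model scores reads purely on matching or
mismatching a substituted base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Variant",
    "HaplotypeDefinition",
    "PhyloTreeDB",
    "load_phylotree",
    "save_phylotree",
    "haplotype_sequence",
    "haplotype_to_haplogroup",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class Variant:
    """A single-base substitution in 1-based reference coordinates."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant position must be >= 1, got {self.position}")
        for label, base in (("ref", self.ref_base), ("alt", self.alt_base)):
            if base not in _BASES:
                raise ValueError(
                    f"{label} allele {base!r} at position {self.position} is not a "
                    "single A/C/G/T substitution (insertions, deletions and "
                    "back-mutation notation are not supported)"
                )
        if self.ref_base == self.alt_base:
            raise ValueError(
                f"ref and alt are both {self.ref_base!r} at position {self.position}"
            )


@dataclass(frozen=True)
class HaplotypeDefinition:
    """A named haplotype: a set of defining variants, unique by position."""

    name: str
    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        positions = [v.position for v in self.variants]
        if len(set(positions)) != len(positions):
            raise ValueError(f"haplotype {self.name!r} has two variants at one position")
        object.__setattr__(self, "variants", tuple(sorted(self.variants)))


@dataclass(frozen=True)
class PhyloTreeDB:
    """A validated collection of haplotype definitions against one reference.

    ``haplogroup_labels`` is the ordered vocabulary used by
    :func:`haplotype_to_haplogroup` for longest-prefix rollup; it may be empty
    if no grouping is needed.
    """

    reference_id: str
    genome_length: int
    haplotypes: Mapping[str, HaplotypeDefinition]
    haplogroup_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        for hap in self.haplotypes.values():
            for v in hap.variants:
                if v.position > self.genome_length:
                    raise ValueError(
                        f"haplotype {hap.name!r}: variant position {v.position} "
                        f"exceeds genome length {self.genome_length}"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.haplotypes)

    def __len__(self) -> int:
        return len(self.haplotypes)


def _build_db(
    records: Iterable[tuple[str, int | None, str | None, str | None]],
    *,
    genome_length: int,
    reference_id: str,
    haplogroup_labels: Sequence[str],
) -> PhyloTreeDB:
    by_name: dict[str, list[Variant]] = {}
    order: list[str] = []
    for name, pos, ref, alt in records:
        if name not in by_name:
            by_name[name] = []
            order.append(name)
        if pos is not None:
            by_name[name].append(Variant(pos, ref, alt))
    haplotypes = {n: HaplotypeDefinition(n, tuple(by_name[n])) for n in order}
    return PhyloTreeDB(
        reference_id=reference_id,
        genome_length=genome_length,
        haplotypes=haplotypes,
        haplogroup_labels=tuple(haplogroup_labels),
    )


def load_phylotree(
    path: str | Path,
    genome_length: int,
    *,
    reference_id: str = "reference",
    haplogroup_labels: Sequence[str] = (),
) -> PhyloTreeDB:
    """Load a haplotype-definition database from TSV or JSON.

    TSV dialect: columns ``haplotype``, ``position``, ``ref``, ``alt``
    (one row per variant), UTF-8, ``#`` comment lines ignored. JSON dialect:
    an array of ``{"name": ..., "variants": [[position, ref, alt], ...]}``
    objects. A converter for real PhyloTree Build 17 exports would emit this
    dialect; it is not bundled.

    Raises ``ValueError`` on duplicate haplotype names, out-of-range
    positions, non-substitution alleles or ref == alt.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    records: list[tuple[str, int, str, str]] = []
    seen_complete: set[str] = set()
    if path.suffix.lower() == ".json":
        for entry in json.loads(text):
            name = entry["name"]
            if name in seen_complete:
                raise ValueError(f"duplicate haplotype name {name!r} in {path}")
            seen_complete.add(name)
            if entry["variants"]:
                for pos, ref, alt in entry["variants"]:
                    records.append((name, int(pos), str(ref), str(alt)))
            else:
                # variant-free haplotype: identical to the reference, still a
                # legal database entry
                records.append((name, None, None, None))
    else:
        header: list[str] | None = None
        last_name: str | None = None
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["haplotype", "position", "ref", "alt"]
                if header != expected:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {expected}, got {header}"
                    )
                continue
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            name, pos_s, ref, alt = fields
            # a haplotype's rows must be contiguous; a name reappearing after
            # another haplotype's rows means the file lists it twice
            if name != last_name:
                if name in seen_complete:
                    raise ValueError(f"duplicate haplotype name {name!r} in {path}")
                seen_complete.add(name)
                last_name = name
            records.append((name, int(pos_s), ref, alt))
    db = _build_db(
        records,
        genome_length=genome_length,
        reference_id=reference_id,
        haplogroup_labels=haplogroup_labels,
    )
    return db


def save_phylotree(db: PhyloTreeDB, path: str | Path) -> None:
    """Write a database in the TSV dialect (round-trips with load_phylotree)."""
    path = Path(path)
    lines = ["haplotype\tposition\tref\talt"]
    for hap in db.haplotypes.values():
        for v in hap.variants:
            lines.append(f"{hap.name}\t{v.position}\t{v.ref_base}\t{v.alt_base}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def haplotype_sequence(db: PhyloTreeDB, reference: str, name: str) -> str:
    """Materialize a haplotype's full sequence from the reference.

    Substitutes each defining variant's alt base into the reference
    (1-based coordinates). Raises if the haplotype is unknown, the reference
    length disagrees with the database, or a variant's stated ref base does
    not match the reference at that position.
    """
    if name not in db.haplotypes:
        raise KeyError(f"unknown haplotype {name!r}")
    if len(reference) != db.genome_length:
        raise ValueError(
            f"reference length {len(reference)} != database genome_length "
            f"{db.genome_length}"
        )
    seq = list(reference)
    for v in db.haplotypes[name].variants:
        if seq[v.position - 1] != v.ref_base:
            raise ValueError(
                f"haplotype {name!r}: reference has {seq[v.position - 1]!r} at "
                f"position {v.position}, definition expects {v.ref_base!r}"
            )
        seq[v.position - 1] = v.alt_base
    return "".join(seq)


def haplotype_to_haplogroup(name: str, db: PhyloTreeDB) -> str:
    """Map a haplotype name to the longest matching haplogroup-label prefix.

    Total function: returns ``"other"`` when no label is a prefix of the name.
    """
    best = ""
    for label in db.haplogroup_labels:
        if name.startswith(label) and len(label) > len(best):
            best = label
    return best or "other"
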