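"""Census-to-ancestry conversion and haplogroup rollup.

Where a city's mtDNA haplogroup distribution is unknown, its census ethnicity
fractions can be converted into expected fractions of four broad
biogeographic ancestry categories (African, West Eurasian, East Asian,
Native American, plus a residual "other") using a per-ethnicity table of
ancestry-category haplogroup frequencies. Sewage-derived haplogroup
compositions are rolled up to the same four categories so the two views are
directly comparable; the comparison metric is total variation distance.

The frequency table is a required input, not baked in: publish-quality
frequency estimates (e.g. per self-reported US ethnicity) belong to their
sources, and tests ship only a clearly synthetic example.

One convention is hard-wired: if the census includes an "Asian" ethnicity and
the frequency table has no row for it, an identity row onto East Asian
ancestry is synthesized — i.e. self-reported Asian ethnicity is assumed to
map entirely to the East Asian mtDNA ancestry group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .deconvolution import HaplogroupComposition

__all__ = [
    "ANCESTRY_CATEGORIES",
    "EthnicityComposition",
    "AncestryFrequencyTable",
    "AncestryComposition",
    "census_to_ancestry",
    "haplogroups_to_ancestry",
    "compare_compositions",
    "load_census",
    "load_frequency_table",
    "load_category_map",
]

ANCESTRY_CATEGORIES = (
    "African",
    "West Eurasian",
    "East Asian",
    "Native American",
    "other",
)

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class EthnicityComposition:
    """Census ethnicity fractions for one city (non-negative, sum to 1)."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("ethnicity fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"ethnicity fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class AncestryFrequencyTable:
    """Per-ethnicity row of ancestry-category haplogroup frequencies.

    Every row is a distribution over :data:`ANCESTRY_CATEGORIES`
    (row-stochastic within 1e-6).
    """

    rows: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for ethnicity, row in self.rows.items():
            unknown = set(row) - set(ANCESTRY_CATEGORIES)
            if unknown:
                raise ValueError(
                    f"row {ethnicity!r} uses unknown categories {sorted(unknown)}; "
                    f"allowed: {list(ANCESTRY_CATEGORIES)}"
                )
            if any(v < 0 for v in row.values()):
                raise ValueError(f"row {ethnicity!r} has negative frequencies")
            total = sum(row.values())
            if abs(total - 1.0) > _SUM_TOL:
                raise ValueError(f"row {ethnicity!r} sums to {total}, expected 1")


@dataclass(frozen=True)
class AncestryComposition:
    """Fractions over the four ancestry categories plus "other"."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(ANCESTRY_CATEGORIES)
        if unknown:
            raise ValueError(
                f"unknown ancestry categories {sorted(unknown)}; "
                f"allowed: {list(ANCESTRY_CATEGORIES)}"
            )
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("ancestry fractions must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.fractions.values()))


_ASIAN_IDENTITY_ROW = {
    "African": 0.0,
    "West Eurasian": 0.0,
    "East Asian": 1.0,
    "Native American": 0.0,
    "other": 0.0,
}


def census_to_ancestry(
    census: EthnicityComposition, table: AncestryFrequencyTable
) -> AncestryComposition:
    """Convert census ethnicity fractions into ancestry-category fractions.

    Linear mixing: ``c_a = sum_k e_k * F[k, a]``. An "Asian" census entry
    missing from the table gets the synthesized identity row onto East Asian
    ancestry; any other missing ethnicity is an error.
    """
    rows = dict(table.rows)
    missing = [e for e in census.fractions if e not in rows]
    if "Asian" in missing:
        rows["Asian"] = _ASIAN_IDENTITY_ROW
        missing.remove("Asian")
    if missing:
        raise ValueError(f"no frequency-table row for ethnicities: {sorted(missing)}")
    out = {cat: 0.0 for cat in ANCESTRY_CATEGORIES}
    for ethnicity, weight in census.fractions.items():
        for cat in ANCESTRY_CATEGORIES:
            out[cat] += weight * rows[ethnicity].get(cat, 0.0)
    return AncestryComposition(fractions={c: v for c, v in out.items() if v > 0 or c != "other"})


def haplogroups_to_ancestry(
    comp: HaplogroupComposition | Mapping[str, float],
    category_map: Mapping[str, str],
) -> AncestryComposition:
    """Roll a haplogroup composition up to the four ancestry categories.

    Haplogroups absent from ``category_map`` contribute to "other"; total
    mass is conserved under any map.
    """
    fractions = comp.fractions if isinstance(comp, HaplogroupComposition) else comp
    bad_targets = set(category_map.values()) - set(ANCESTRY_CATEGORIES)
    if bad_targets:
        raise ValueError(
            f"category map targets unknown categories {sorted(bad_targets)}"
        )
    out: dict[str, float] = {}
    for group, mass in fractions.items():
        category = category_map.get(group, "other")
        out[category] = out.get(category, 0.0) + float(mass)
    return AncestryComposition(fractions=out)


def compare_compositions(a: AncestryComposition, b: AncestryComposition) -> float:
    """Total variation distance between two ancestry compositions, in [0, 1].

    The category union is taken; categories missing from one side count as 0.
    Symmetric; 0 for identical compositions, 1 for disjoint supports.
    """
    categories = set(a.fractions) | set(b.fractions)
    return 0.5 * sum(
        abs(a.fractions.get(c, 0.0) - b.fractions.get(c, 0.0)) for c in categories
    )


def load_census(path: str | Path) -> EthnicityComposition:
    """TSV with columns ``ethnicity`` and ``fraction``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return EthnicityComposition(
        fractions=dict(zip(df["ethnicity"].astype(str), df["fraction"].astype(float)))
    )


def load_frequency_table(path: str | Path) -> AncestryFrequencyTable:
    """TSV with an ``ethnicity`` column and one column per ancestry category."""
    df = pd.read_csv(path, sep="\t", comment="#")
    rows = {}
    for _, record in df.iterrows():
        ethnicity = str(record["ethnicity"])
        rows[ethnicity] = {
            col: float(record[col]) for col in df.columns if col != "ethnicity"
        }
    return AncestryFrequencyTable(rows=rows)


def load_category_map(path: str | Path) -> dict[str, str]:
    """TSV with columns ``haplogroup`` and ``category``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["haplogroup"].astype(str), df["category"].astype(str)))
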