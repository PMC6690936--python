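"""Sample embedding: consensus sequences, one-hot PCA, NJ trees, bootstrap.

A pooled sample is summarized as a single consensus sequence — the dominant
base per position for PCA, or an ambiguity-coded variant (R/Y/N) for
phylogenetics. Dominant-base consensuses are one-hot encoded into a
(n_samples, 4 * genome_length) matrix and projected onto the leading
principal components; ambiguity-coded consensuses feed p-distance
neighbor-joining trees whose clades are scored by column-resampling
bootstrap.

Consensus calling deliberately fuses haplotypes: a pooled sample's consensus
is a chimera of its contributors, which is exactly why the mixture EM exists;
these embeddings are exploratory views, not composition estimates.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj
from sklearn.decomposition import PCA

from .readmodel import SampleAlignment

__all__ = [
    "ConsensusSequence",
    "OneHotMatrix",
    "EmbeddingResult",
    "base_counts",
    "consensus",
    "one_hot_encode",
    "pca",
    "p_distance",
    "nj_tree",
    "nj_from_distances",
    "tree_bipartitions",
    "bootstrap_support",
]

logger = logging.getLogger(__name__)

_BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class ConsensusSequence:
    """Per-position consensus symbols for one sample.

    ``mode`` is "dominant" (A/C/G/T only) or "ambiguity" (A/C/G/T/R/Y/N).
    """

    sample_id: str
    bases: str
    mode: str = "dominant"


@dataclass(frozen=True)
class OneHotMatrix:
    """0/1 matrix of shape (n_samples, 4 * genome_length), position-major,
    channel order A, C, G, T; exactly one 1 per position per row."""

    values: np.ndarray
    sample_ids: tuple[str, ...]


@dataclass(frozen=True)
class EmbeddingResult:
    projections: np.ndarray  # (n_samples, k)
    explained_variance_ratio: np.ndarray  # (k,), non-increasing, sums <= 1
    sample_ids: tuple[str, ...]


def base_counts(sample: SampleAlignment) -> np.ndarray:
    """Pileup: per-position counts of A, C, G, T (N observations ignored)."""
    counts = np.zeros((sample.genome_length, 4), dtype=np.int64)
    for frag in sample.fragments:
        for base, col in _BASE_INDEX.items():
            sel = frag.bases == base
            if sel.any():
                np.add.at(counts[:, col], frag.positions[sel] - 1, 1)
    return counts


def consensus(
    counts: np.ndarray,
    reference: str,
    mode: str = "dominant",
    ambiguity_fraction: float = 0.25,
    sample_id: str = "consensus",
) -> ConsensusSequence:
    """Call a consensus from per-position base counts.

    Dominant mode takes the highest-count base, ties broken in fixed order
    A < C < G < T; zero-coverage positions fall back to the reference base
    (logged) so every position carries exactly one unambiguous symbol.
    Ambiguity mode additionally codes genuinely mixed positions: when the
    second base reaches ``ambiguity_fraction`` of the position's coverage,
    the call becomes R (both top bases purines), Y (both pyrimidines) or N.
    """
    counts = np.asarray(counts)
    if counts.shape != (len(reference), 4):
        raise ValueError("counts must have shape (genome_length, 4)")
    if np.any(counts < 0):
        raise ValueError("negative base counts")
    if mode not in ("dominant", "ambiguity"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    reference = reference.upper()
    totals = counts.sum(axis=1)
    order = np.argsort(-counts, axis=1, kind="stable")  # ties keep A<C<G<T order
    top = order[:, 0]
    second = order[:, 1]
    out = np.array([_BASE_ORDER[i] for i in top])
    uncovered = totals == 0
    if uncovered.any():
        logger.warning(
            "consensus %s: %d zero-coverage positions fall back to the reference",
            sample_id,
            int(uncovered.sum()),
        )
        out[uncovered] = np.frombuffer(reference.encode(), dtype="S1").astype("U1")[
            uncovered
        ]
    if mode == "ambiguity":
        with np.errstate(invalid="ignore", divide="ignore"):
            second_frac = np.where(
                totals > 0, counts[np.arange(len(counts)), second] / np.maximum(totals, 1), 0.0
            )
        mixed = (second_frac >= ambiguity_fraction) & ~uncovered
        for p in np.flatnonzero(mixed):
            b1, b2 = _BASE_ORDER[top[p]], _BASE_ORDER[second[p]]
            if {b1, b2} <= _PURINES:
                out[p] = "R"
            elif {b1, b2} <= _PYRIMIDINES:
                out[p] = "Y"
            else:
                out[p] = "N"
    return ConsensusSequence(sample_id=sample_id, bases="".join(out), mode=mode)


def one_hot_encode(consensuses: Sequence[ConsensusSequence]) -> OneHotMatrix:
    """Encode dominant-mode consensuses as a (n, 4L) 0/1 matrix."""
    if not consensuses:
        raise ValueError("no consensuses to encode")
    lengths = {len(c.bases) for c in consensuses}
    if len(lengths) > 1:
        raise ValueError("consensuses have unequal lengths")
    (length,) = lengths
    values = np.zeros((len(consensuses), 4 * length), dtype=np.uint8)
    for row, cons in enumerate(consensuses):
        for pos, base in enumerate(cons.bases):
            if base not in _BASE_INDEX:
                raise ValueError(
                    f"sample {cons.sample_id!r} has ambiguity symbol {base!r} at "
                    f"position {pos + 1}; one-hot encoding needs dominant-mode "
                    "consensuses"
                )
            values[row, 4 * pos + _BASE_INDEX[base]] = 1
    return OneHotMatrix(values=values, sample_ids=tuple(c.sample_id for c in consensuses))


def pca(matrix: OneHotMatrix, k: int = 2) -> EmbeddingResult:
    """Project samples onto the top-k principal directions.

    Columns are mean-centered but not scaled (scaling would blow up the
    constant-site columns that dominate a one-hot genotype matrix). A matrix
    with no variance at all (identical rows) yields zero projections and zero
    explained-variance ratios.
    """
    X = matrix.values.astype(np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    centered = X - X.mean(axis=0)
    if not np.any(centered):
        return EmbeddingResult(
            projections=np.zeros((n, k)),
            explained_variance_ratio=np.zeros(k),
            sample_ids=matrix.sample_ids,
        )
    model = PCA(n_components=k, svd_solver="full")
    proj = model.fit_transform(X)
    return EmbeddingResult(
        projections=proj,
        explained_variance_ratio=model.explained_variance_ratio_,
        sample_ids=matrix.sample_ids,
    )


def _encode_for_distance(consensuses: Sequence[ConsensusSequence]) -> np.ndarray:
    """Sequences as int8 codes, -1 for any non-ACGT symbol."""
    n = len(consensuses)
    length = len(consensuses[0].bases)
    codes = np.full((n, length), -1, dtype=np.int8)
    for i, cons in enumerate(consensuses):
        arr = np.frombuffer(cons.bases.encode(), dtype="S1").astype("U1")
        for base, idx in _BASE_INDEX.items():
            codes[i, arr == base] = idx
    return codes


def p_distance(a: ConsensusSequence, b: ConsensusSequence) -> float:
    """Fraction of differing sites among sites where both symbols are ACGT."""
    codes = _encode_for_distance([a, b])
    return float(_pairwise_p_distance(codes)[0, 1])


def _pairwise_p_distance(codes: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    dist = np.zeros((n, n))
    valid = codes >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            denom = int(both.sum())
            if denom == 0:
                raise ValueError(
                    f"no unambiguous overlapping sites between sequences {i} and {j}"
                )
            dist[i, j] = dist[j, i] = (codes[i][both] != codes[j][both]).sum() / denom
    return dist


def nj_from_distances(dist: np.ndarray, ids: Sequence[str]):
    """Canonical neighbor joining on a distance matrix (scikit-bio TreeNode).

    Negative intermediate branch lengths are clamped to zero.
    """
    dm = DistanceMatrix(dist, ids=list(ids))
    return nj(dm)


def nj_tree(consensuses: Sequence[ConsensusSequence]) -> str:
    """Neighbor-joining tree over consensus sequences, as a newick string.

    Distances are p-distances over mutually unambiguous sites. Taxa are
    ordered lexicographically by sample id before agglomeration, making
    tie-breaks deterministic.
    """
    if len(consensuses) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    lengths = {len(c.bases) for c in consensuses}
    if len(lengths) > 1:
        raise ValueError("sequences have unequal lengths")
    ordered = sorted(consensuses, key=lambda c: c.sample_id)
    codes = _encode_for_distance(ordered)
    dist = _pairwise_p_distance(codes)
    tree = nj_from_distances(dist, [c.sample_id for c in ordered])
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def tree_bipartitions(tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (unrooted) tree, each canonicalized as
    the tip set NOT containing the lexicographically smallest taxon."""
    all_tips = frozenset(t.name for t in tree.tips())
    anchor = min(all_tips)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            parts.add(side)
    return parts


def newick_bipartitions(newick: str) -> set[frozenset[str]]:
    """Bipartitions of a newick string (convenience for comparing trees)."""
    from skbio import TreeNode

    return tree_bipartitions(TreeNode.read(io.StringIO(newick)))


def bootstrap_support(
    consensuses: Sequence[ConsensusSequence],
    replicates: int = 1000,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Clade robustness by column-resampling bootstrap.

    Alignment columns are resampled with replacement ``replicates`` times;
    each replicate's NJ tree is compared against the original tree, and every
    original internal bipartition is scored by the fraction of replicate
    trees that contain it. Reproducible under ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(consensuses) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    ordered = sorted(consensuses, key=lambda c: c.sample_id)
    ids = [c.sample_id for c in ordered]
    codes = _encode_for_distance(ordered)
    length = codes.shape[1]
    original = nj_from_distances(_pairwise_p_distance(codes), ids)
    targets = tree_bipartitions(original)
    hits = {part: 0 for part in targets}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        replicate = nj_from_distances(_pairwise_p_distance(codes[:, cols]), ids)
        found = tree_bipartitions(replicate)
        for part in targets:
            if part in found:
                hits[part] += 1
    return {part: hits[part] / replicates for part in targets}
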