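"""Mixture deconvolution of pooled mitochondrial reads.

Each read is scored against every candidate haplotype with a substitution
sequencing-error model: at each observed base that falls on a defining-variant
site, the read contributes ``log(1 - eps)`` if it matches the haplotype's
allele there (the alt base if the haplotype carries the variant, the
reference base otherwise) and ``log(eps / 3)`` if it contradicts it, with
``eps`` the base's own Phred-derived error probability. Observations at
non-defining sites and N bases are uninformative and contribute nothing, so a
read covering no defining site has an identical score for every haplotype.

Mixture proportions are then estimated by expectation maximization over the
read-by-haplotype log-likelihood matrix:

    E-step:  gamma(r, h) = p_h * exp(L[r, h]) / sum_h' p_h' * exp(L[r, h'])
    M-step:  p_h = (1 / R) * sum_r gamma(r, h)

initialized from a symmetric Dirichlet draw and iterated until the total
log-likelihood changes by less than ``tol``. After convergence the candidate
set is reduced to the haplotypes that pass a proportion floor and a minimum
best-assigned-read count, and the EM is rerun on the survivors only; the
restricted run's proportions are the final composition.

The same algorithm is exposed as :class:`MixtureEM`, a scikit-learn
estimator over the log-likelihood matrix, and as the module-level functions
(:func:`run_em`, :func:`deconvolve`, ...) that operate on the pipeline's
domain objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .phylotree import PhyloTreeDB, haplotype_to_haplogroup
from .readmodel import SampleAlignment

__all__ = [
    "ConsistencyMatrix",
    "EMConfig",
    "MixtureEstimate",
    "HaplogroupComposition",
    "MixtureEM",
    "consistency_matrix",
    "init_proportions",
    "run_em",
    "filter_contributors",
    "deconvolve",
    "aggregate_haplogroups",
]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class ConsistencyMatrix:
    """Read-by-haplotype log-likelihoods under the error model above."""

    log_values: np.ndarray  # (n_reads, n_haplotypes), finite
    reads: tuple[str, ...]
    haplotypes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.log_values.shape != (len(self.reads), len(self.haplotypes)):
            raise ValueError("log_values shape disagrees with read/haplotype labels")
        if not np.all(np.isfinite(self.log_values)):
            raise ValueError("consistency matrix contains non-finite entries")


@dataclass(frozen=True)
class EMConfig:
    """Knobs of the EM and the contributor filter.

    ``low_coverage_mode`` relaxes the read-support requirement to a single
    best-assigned read, for samples where even true contributors may back
    only a handful of reads.
    """

    alpha: float = 1.0
    seed: int = 0
    tol: float = 1e-4
    max_iter: int = 1000
    min_prop: float = 0.01
    min_reads: int = 2
    low_coverage_mode: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not 0 <= self.min_prop < 1:
            raise ValueError("min_prop must be in [0, 1)")

    @property
    def effective_min_reads(self) -> int:
        return 1 if self.low_coverage_mode else self.min_reads


@dataclass(frozen=True)
class MixtureEstimate:
    """Converged mixture proportions with the likelihood trace.

    ``proportions`` is aligned with ``haplotypes``; after the full two-stage
    deconvolution, haplotypes dropped by the contributor filter carry exact
    zeros and ``contributors`` lists the survivors.
    """

    haplotypes: tuple[str, ...]
    proportions: np.ndarray
    loglik_trace: tuple[float, ...]
    contributors: tuple[str, ...]
    responsibilities: np.ndarray  # (n_reads, n_haplotypes) at convergence

    def proportion_of(self, name: str) -> float:
        return float(self.proportions[self.haplotypes.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {h: float(p) for h, p in zip(self.haplotypes, self.proportions)}


@dataclass(frozen=True)
class HaplogroupComposition:
    """Proportions aggregated to haplogroup labels (unmatched mass: "other")."""

    fractions: Mapping[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.fractions.values()))


def consistency_matrix(
    sample: SampleAlignment, db: PhyloTreeDB, reference: str
) -> ConsistencyMatrix:
    """Score every read against every haplotype in the database."""
    if len(reference) != db.genome_length:
        raise ValueError(
            f"reference length {len(reference)} != database genome_length "
            f"{db.genome_length}"
        )
    reference = reference.upper()
    names = tuple(db.names)
    sites = sorted({v.position for hap in db.haplotypes.values() for v in hap.variants})
    site_pos = np.asarray(sites, dtype=np.int64)
    n_sites = len(sites)
    # allele matrix: haplotype x defining site, alt where carried, ref otherwise
    alleles = np.empty((len(names), n_sites), dtype="U1")
    site_index = {p: i for i, p in enumerate(sites)}
    for row, name in enumerate(names):
        for i, p in enumerate(sites):
            alleles[row, i] = reference[p - 1]
        for v in db.haplotypes[name].variants:
            if reference[v.position - 1] != v.ref_base:
                raise ValueError(
                    f"haplotype {name!r}: definition expects {v.ref_base!r} at "
                    f"position {v.position}, reference has "
                    f"{reference[v.position - 1]!r}"
                )
            alleles[row, site_index[v.position]] = v.alt_base
    log_values = np.zeros((sample.n_reads, len(names)))
    read_ids: list[str] = []
    for r, frag in enumerate(sample.fragments):
        read_ids.append(frag.read_id)
        if n_sites == 0 or len(frag) == 0:
            continue
        idx = np.searchsorted(site_pos, frag.positions)
        idx = np.clip(idx, 0, n_sites - 1)
        on_site = site_pos[idx] == frag.positions
        informative = on_site & np.isin(frag.bases, tuple(_ACGT))
        if not informative.any():
            continue
        obs_bases = frag.bases[informative]
        eps = frag.error_probs[informative]
        cols = idx[informative]
        match = obs_bases[:, None] == alleles.T[cols]  # (n_obs, n_haplotypes)
        contrib = np.where(
            match, np.log1p(-eps)[:, None], np.log(eps / 3.0)[:, None]
        )
        log_values[r] = contrib.sum(axis=0)
    return ConsistencyMatrix(
        log_values=log_values, reads=tuple(read_ids), haplotypes=names
    )


def init_proportions(
    n_haplotypes: int,
    config: EMConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One symmetric Dirichlet(alpha) draw on the (n-1)-simplex.

    Reproducible under ``config.seed``; entries strictly positive (draws that
    underflow to zero are floored and renormalized).
    """
    if n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = rng.dirichlet(np.full(n_haplotypes, config.alpha))
    p = np.clip(p, 1e-12, None)
    return p / p.sum()


def _em_loop(
    log_values: np.ndarray, init: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Core EM iteration; returns (proportions, responsibilities, trace)."""
    n_reads, n_hap = log_values.shape
    if n_reads == 0:
        raise ValueError("empty read set")
    if not np.all(np.isfinite(log_values)):
        raise ValueError("non-finite log-likelihoods")
    p = np.asarray(init, dtype=np.float64)
    trace: list[float] = []
    gamma = np.full((n_reads, n_hap), 1.0 / n_hap)
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            log_w = np.log(p)[None, :] + log_values
        shift = log_w.max(axis=1, keepdims=True)
        w = np.exp(log_w - shift)
        denom = w.sum(axis=1, keepdims=True)
        gamma = w / denom
        loglik = float((shift[:, 0] + np.log(denom[:, 0])).sum())
        p = gamma.mean(axis=0)
        if trace and abs(loglik - trace[-1]) < tol:
            trace.append(loglik)
            break
        trace.append(loglik)
    return p, gamma, trace


def run_em(
    matrix: ConsistencyMatrix, init: np.ndarray, config: EMConfig
) -> MixtureEstimate:
    """Single EM pass over all haplotypes of the matrix (no filtering).

    The per-read posterior is normalized after shifting each row by its
    maximum, so arbitrarily small likelihoods never underflow to an all-zero
    row. The returned trace is the total log-likelihood at each iteration and
    is non-decreasing (standard EM monotonicity).
    """
    if len(init) != len(matrix.haplotypes):
        raise ValueError("init length disagrees with the number of haplotypes")
    p, gamma, trace = _em_loop(matrix.log_values, init, config.tol, config.max_iter)
    return MixtureEstimate(
        haplotypes=matrix.haplotypes,
        proportions=p,
        loglik_trace=tuple(trace),
        contributors=matrix.haplotypes,
        responsibilities=gamma,
    )


def filter_contributors(
    estimate: MixtureEstimate, matrix: ConsistencyMatrix, config: EMConfig
) -> list[str]:
    """Reevaluate which haplotypes are genuinely present.

    A haplotype survives when its proportion is at least ``min_prop`` and at
    least ``min_reads`` reads assign it a posterior above 0.5 (one read in
    low-coverage mode). Never returns an empty set: if nothing passes, the
    single largest-proportion haplotype is kept.
    """
    support = (estimate.responsibilities > 0.5).sum(axis=0)
    retained = [
        h
        for i, h in enumerate(estimate.haplotypes)
        if estimate.proportions[i] >= config.min_prop
        and support[i] >= config.effective_min_reads
    ]
    if not retained:
        retained = [estimate.haplotypes[int(np.argmax(estimate.proportions))]]
    return retained


def deconvolve(
    sample: SampleAlignment, db: PhyloTreeDB, reference: str, config: EMConfig
) -> MixtureEstimate:
    """Full two-stage deconvolution of one sample.

    Stage one runs EM over every haplotype in the database, stage two reruns
    it restricted to the filtered contributors; the final proportions live on
    the survivor set (zeros elsewhere). Deterministic under (seed, inputs).
    """
    matrix = consistency_matrix(sample, db, reference)
    rng = np.random.default_rng(config.seed)
    init_full = init_proportions(len(matrix.haplotypes), config, rng=rng)
    first = run_em(matrix, init_full, config)
    contributors = filter_contributors(first, matrix, config)
    keep = [matrix.haplotypes.index(h) for h in contributors]
    restricted = ConsistencyMatrix(
        log_values=matrix.log_values[:, keep],
        reads=matrix.reads,
        haplotypes=tuple(contributors),
    )
    init_restricted = init_proportions(len(contributors), config, rng=rng)
    final = run_em(restricted, init_restricted, config)
    proportions = np.zeros(len(matrix.haplotypes))
    responsibilities = np.zeros((len(matrix.reads), len(matrix.haplotypes)))
    for j, i in enumerate(keep):
        proportions[i] = final.proportions[j]
        responsibilities[:, i] = final.responsibilities[:, j]
    proportions /= proportions.sum()
    return MixtureEstimate(
        haplotypes=matrix.haplotypes,
        proportions=proportions,
        loglik_trace=final.loglik_trace,
        contributors=tuple(contributors),
        responsibilities=responsibilities,
    )


def aggregate_haplogroups(
    estimate: MixtureEstimate | Mapping[str, float], db: PhyloTreeDB
) -> HaplogroupComposition:
    """Sum haplotype proportions by their haplogroup label.

    Mass on haplotypes matching no label lands under ``"other"``; total mass
    is conserved. Accepts either a :class:`MixtureEstimate` or a plain
    name -> proportion mapping.
    """
    props = estimate.as_dict() if isinstance(estimate, MixtureEstimate) else dict(estimate)
    fractions: dict[str, float] = {}
    for name, p in props.items():
        if p == 0:
            continue
        group = haplotype_to_haplogroup(name, db)
        fractions[group] = fractions.get(group, 0.0) + float(p)
    return HaplogroupComposition(fractions=fractions)


class MixtureEM(BaseEstimator):
    """Scikit-learn estimator form of the two-stage mixture EM.

    Parameters mirror :class:`EMConfig`. ``fit`` consumes ``X``, the
    (n_reads, n_haplotypes) log-likelihood matrix — e.g.
    ``consistency_matrix(...).log_values`` — and learns the mixing weights,
    analogous to how a Gaussian mixture learns component weights from
    per-point component likelihoods.

    Attributes
    ----------
    proportions_ : ndarray of shape (n_haplotypes,)
        Final mixture weights; exact zeros for filtered-out haplotypes.
    contributors_ : ndarray of int
        Column indices retained by the contributor filter.
    responsibilities_ : ndarray of shape (n_reads, n_haplotypes)
        Posterior read-to-haplotype assignments at convergence.
    loglik_trace_ : list of float
        Total log-likelihood per iteration of the final restricted run.
    n_iter_ : int
        Iterations of the final restricted run.
    """

    def __init__(
        self,
        alpha: float = 1.0,
        seed: int = 0,
        tol: float = 1e-4,
        max_iter: int = 1000,
        min_prop: float = 0.01,
        min_reads: int = 2,
        low_coverage_mode: bool = False,
        refit_contributors: bool = True,
    ) -> None:
        self.alpha = alpha
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter
        self.min_prop = min_prop
        self.min_reads = min_reads
        self.low_coverage_mode = low_coverage_mode
        self.refit_contributors = refit_contributors

    def _config(self) -> EMConfig:
        return EMConfig(
            alpha=self.alpha,
            seed=self.seed,
            tol=self.tol,
            max_iter=self.max_iter,
            min_prop=self.min_prop,
            min_reads=self.min_reads,
            low_coverage_mode=self.low_coverage_mode,
        )

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (n_reads, n_haplotypes) matrix")
        if X.shape[0] == 0:
            raise ValueError("empty read set")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite log-likelihoods")
        return X

    def fit(self, X, y=None) -> "MixtureEM":
        X = self._validate(X)
        config = self._config()
        n_reads, n_hap = X.shape
        names = tuple(str(i) for i in range(n_hap))
        matrix = ConsistencyMatrix(X, tuple(f"r{i}" for i in range(n_reads)), names)
        rng = np.random.default_rng(config.seed)
        init = init_proportions(n_hap, config, rng=rng)
        first = run_em(matrix, init, config)
        if self.refit_contributors:
            contributors = filter_contributors(first, matrix, config)
            keep = np.array([names.index(h) for h in contributors], dtype=int)
            restricted = ConsistencyMatrix(
                X[:, keep], matrix.reads, tuple(contributors)
            )
            init2 = init_proportions(len(keep), config, rng=rng)
            final = run_em(restricted, init2, config)
            proportions = np.zeros(n_hap)
            gamma = np.zeros((n_reads, n_hap))
            proportions[keep] = final.proportions
            gamma[:, keep] = final.responsibilities
            proportions /= proportions.sum()
        else:
            keep = np.arange(n_hap)
            final = first
            proportions = first.proportions
            gamma = first.responsibilities
        self.n_features_in_ = n_hap
        self.proportions_ = proportions
        self.contributors_ = keep
        self.responsibilities_ = gamma
        self.loglik_trace_ = list(final.loglik_trace)
        self.n_iter_ = len(final.loglik_trace)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior read-to-haplotype responsibilities under the fitted weights."""
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of haplotype columns than fit")
        with np.errstate(divide="ignore"):
            log_w = np.where(
                self.proportions_ > 0, np.log(np.clip(self.proportions_, 1e-300, None)), -np.inf
            )[None, :] + X
        shift = log_w.max(axis=1, keepdims=True)
        w = np.exp(log_w - shift)
        return w / w.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """Most likely origin haplotype index per read."""
        return np.argmax(self.predict_proba(X), axis=1)


def config_to_dict(config: EMConfig) -> dict:
    """Resolved config as a JSON-serializable dict (for run reports)."""
    return {
        "alpha": config.alpha,
        "seed": config.seed,
        "tol": config.tol,
        "max_iter": config.max_iter,
        "min_prop": config.min_prop,
        "min_reads": config.min_reads,
        "low_coverage_mode": config.low_coverage_mode,
    }
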