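# Methods

This note describes the statistical model and the numerical choices behind
`mitopool`, in the package's own terms.

## Problem setting

A pooled DNA sample (e.g., mtDNA-enriched sequencing of municipal wastewater)
contains reads drawn from many individual mitochondrial genomes. Each genome
belongs to a haplotype: a known set of single-nucleotide substitutions relative
to a reference sequence, organized in a phylogeny whose major clades are
haplogroups. The goal is to estimate the proportion vector **p** over a panel
of candidate haplotypes from which the reads were drawn, and to summarize the
result at the haplogroup level.

## Read consistency model

For a read *r* and haplotype *h*, the consistency score is a log-likelihood
accumulated only over the reference positions covered by *r* at which any
haplotype in the panel defines a variant:

- if the read base equals the base haplotype *h* carries at that position
  (variant allele if *h* defines a variant there, reference base otherwise):
  add `log(1 − ε)`;
- otherwise add `log(ε / 3)`, treating the three possible wrong bases as
  equally likely;
- `N` bases and positions where no panel haplotype defines a variant
  contribute 0.

ε is the per-base error probability derived from the Phred quality,
`ε = 10^(−Q/10)`. Reads covering no defining site have identical scores for
all haplotypes and are uninformative; they do not bias the estimate because
the model below only uses score *differences* between haplotypes.

## Mixture deconvolution by EM

Given the n_reads × n_haplotypes matrix `L` of consistency log-likelihoods,
the reads are modeled as i.i.d. draws from a mixture: read *r* originates from
haplotype *h* with probability `p_h`, and then has likelihood `exp(L[r, h])`.
The log-likelihood `Σ_r log Σ_h p_h exp(L[r, h])` is maximized by EM:

- **E step**: responsibilities `γ(r, h) ∝ p_h · exp(L[r, h])`, computed with a
  per-row maximum shift for numerical stability;
- **M step**: `p_h = mean_r γ(r, h)`.

Initial proportions are drawn from a symmetric Dirichlet(α = 1) with a fixed
seed; iteration stops when the log-likelihood improves by less than `tol`
(default 1e-4) or after `max_iter` (default 1000) iterations. Because the
objective is concave in **p** (a sum of logs of linear functions), EM reaches
the global maximum; the test suite verifies this against an exhaustive
0.001-step grid search over the simplex on small instances, and verifies that
the log-likelihood trace is non-decreasing on randomized instances.

### Two-stage contributor filtering

A single EM pass tends to leave small spurious mass on absent haplotypes. The
estimator therefore runs a second pass: a haplotype is kept as a *contributor*
if its estimated proportion is at least `min_prop` (default 0.01) **and** at
least `min_reads` (default 2) reads assign it a responsibility above 0.5. In
`low_coverage_mode` the read-support requirement drops to 1. If no haplotype
survives, the single best-supported haplotype is kept. EM is then re-run
restricted to the contributors, and dropped haplotypes are reported with
proportion exactly 0. On simulated 70/25/5 % mixtures at 200× coverage with a
0.5 % error rate, this recovers proportions with mean absolute error well
under 0.03 and retains the 5 % trace contributor.

### Haplogroup aggregation

Haplotype names map to haplogroup labels by longest matching prefix from a
user-supplied label list (e.g., `H1a` → `H` unless `H1` is listed); unmatched
names roll up to `other`. Proportions are summed within labels.

## Coverage filtering and pooling

Coverage is the per-position read depth over the full genome, including
zero-depth positions. A sample passes quality control when its mean coverage
is at least 10× (inclusive). Samples from the same treatment plant are pooled
by concatenating fragments (read ids are prefixed with the sample id to stay
unique); mean coverage is additive under pooling.

## Homology masking

To guard against reads from a related non-human mitochondrial genome, the
package flags every reference position that lies inside a `window`-length
substring (default 19 bp) shared exactly between the two genomes. 19 bp is the
minimum exact seed a typical seed-and-extend short-read aligner requires, so
unflagged regions cannot attract cross-mapping reads. The scan is exact
(hash-set of all windows of one genome, linear scan of the other), forward
strand by default, with a reverse-complement-aware variant available. A
uniqueness summary and BED export (0-based, half-open) are provided, along
with set arithmetic for classifying reads that aligned to both references.

## Consensus, embedding, and trees

Per-sample consensus sequences are called from per-position base counts:
the dominant base wins (ties broken alphabetically A<C<G<T; zero-coverage
positions fall back to the reference base), or, in ambiguity mode, a second
base reaching 25 % of the depth yields an IUPAC code (R/Y for the two
transitions, N otherwise). Consensus sequences are one-hot encoded
position-major (4 columns per position, ACGT order), giving 4 × 16,569 =
66,276 columns over the human mitochondrial genome. PCA is mean-centered and
unscaled (full SVD); degenerate inputs (all rows identical) yield zero
projections rather than an error.

Between-sample distances are p-distances over sites where both sequences have
unambiguous A/C/G/T calls. Trees are built by neighbor joining with negative
branch lengths clamped to zero. Bootstrap support resamples alignment columns
with replacement, rebuilds the tree, and reports for each internal bipartition
of the original tree the fraction of replicates containing it. Bipartitions
are canonicalized as the side not containing the lexicographically smallest
taxon.

## Census comparison

Ancestry is summarized over five fixed categories: African, West Eurasian,
East Asian, Native American, other. A census ethnicity composition **c** is
converted to expected mitochondrial ancestry by a linear map `a = Fᵀ c`,
where row `F[k, ·]` gives the mitochondrial ancestry frequencies of
self-reported ethnicity *k*. An `Asian → East Asian` identity row is
synthesized automatically when absent. Estimated haplogroup mixtures roll up
to the same categories through a haplogroup → category map (unmapped
haplogroups go to `other`). Compositions are compared by total variation
distance, `TVD = ½ Σ |a_i − b_i|`.

## Synthetic data

The simulators are designed so every downstream guarantee is testable:

- `simulate_phylotree` builds a panel of haplotypes with *private* variants at
  globally distinct positions, so pairwise Hamming distances are known exactly
  (haplotypes `S1a, S2a, …` under haplogroup labels `S1, S2, …`).
- `simulate_mixture_reads` draws `round(coverage · L / read_length)` reads
  with uniform start positions, origins sampled from the target proportions,
  and uniform per-base errors at the requested rate (qualities match the rate
  exactly, capped at Phred 60 for error-free simulation). Output is SAM and/or
  FASTQ plus a ground-truth record of each read's origin.
- `simulate_contaminant` mutates the reference everywhere outside specified
  preserved windows at a given divergence, then verifies with the homology
  mask that exactly the intended windows (those at least one mask window long)
  are flagged, resampling a bounded number of times if a shared window arises
  by chance.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng` with explicit seeds;
  pipeline stages derive per-sample seeds from the run seed.
- EM rows are max-shifted before exponentiation; proportions are clipped at
  1e-12 and renormalized to avoid log-of-zero.
- Problem sizes in tests and the acceptance script (2 kb toy genomes, 5
  haplotypes, 200× coverage, 20 replicates) are chosen to finish in seconds
  while leaving the statistical claims falsifiable; the encoding-width check
  uses the real 16,569 bp genome length.

## Limitations

- The consistency model ignores indels and assumes independent per-base
  errors; alignment artifacts near structural variants are not modeled.
- Haplotypes differing only at sites with no read coverage are not
  identifiable; the estimator then splits mass arbitrarily between them
  (their *sum* remains stable), which is the expected behavior for a mixture
  likelihood.
- The census conversion is a linear approximation using externally supplied
  frequency tables; the package ships no demographic estimates of its own,
  and test tables are explicitly synthetic.
- Homology masking is exact-match only; diverged-but-mappable regions below
  the window length are not flagged.
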