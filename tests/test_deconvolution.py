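import numpy as np
import pytest
from sklearn.base import clone

from conftest import make_fragment, make_sample
from mitopool.deconvolution import (
    ConsistencyMatrix,
    EMConfig,
    MixtureEM,
    aggregate_haplogroups,
    consistency_matrix,
    deconvolve,
    filter_contributors,
    init_proportions,
    run_em,
)
from mitopool.phylotree import HaplotypeDefinition, PhyloTreeDB, Variant
from mitopool.readmodel import read_sam
from mitopool.synthetic import simulate_mixture_reads, simulate_phylotree


def grid_search_max_loglik(log_values: np.ndarray, step: float = 0.001):
    """Independent oracle: exhaustive simplex grid search of the mixture
    log-likelihood (concave in the proportions, so the grid max is within
    O(step) of the true max)."""
    n_hap = log_values.shape[1]
    shift = log_values.max(axis=1, keepdims=True)
    w = np.exp(log_values - shift)  # (R, H), strictly positive
    const = float(shift.sum())
    steps = round(1 / step)
    if n_hap == 2:
        t = np.arange(steps + 1) / steps
        grid = np.column_stack([t, 1 - t])
    elif n_hap == 3:
        pts = []
        for i in range(steps + 1):
            j = np.arange(steps - i + 1)
            pts.append(np.column_stack([np.full(len(j), i), j, steps - i - j]))
        grid = np.vstack(pts) / steps
    else:
        raise ValueError("oracle supports 2 or 3 haplotypes")
    best_ll, best_p = -np.inf, None
    for chunk in np.array_split(grid, max(1, len(grid) // 20000)):
        ll = np.log(chunk @ w.T).sum(axis=1)
        i = int(np.argmax(ll))
        if ll[i] > best_ll:
            best_ll, best_p = float(ll[i]), chunk[i]
    return best_ll + const, best_p


def random_instance(rng, n_reads, n_hap):
    """A random but well-behaved log-likelihood matrix."""
    return np.log(rng.uniform(0.01, 1.0, size=(n_reads, n_hap)))


class TestConsistencyMatrix:
    def _db(self):
        # defining sites at 10 (h1: A->G) and 20 (h2: C->T) on a 50 bp genome
        reference = "A" * 9 + "A" + "C" * 10 + "G" * 30
        haplotypes = {
            "h1": HaplotypeDefinition("h1", (Variant(10, "A", "G"),)),
            "h2": HaplotypeDefinition("h2", (Variant(20, "C", "T"),)),
        }
        return reference, PhyloTreeDB("r", 50, haplotypes)

    def test_single_site_match_and_mismatch(self):
        reference, db = self._db()
        # one read covering only site 10, observing the h1 alt base, Q=30
        frag = make_fragment("r1", 10, "G", q=30.0)
        sample = make_sample([frag], genome_length=50, reference_id="r")
        matrix = consistency_matrix(sample, db, reference)
        eps = 1e-3
        row = matrix.log_values[0]
        by_name = dict(zip(matrix.haplotypes, row))
        assert by_name["h1"] == pytest.approx(np.log1p(-eps))
        assert by_name["h2"] == pytest.approx(np.log(eps / 3))

    def test_read_off_defining_sites_is_uninformative(self):
        reference, db = self._db()
        frag = make_fragment("r1", 30, "GGGGG", q=30.0)
        sample = make_sample([frag], genome_length=50, reference_id="r")
        matrix = consistency_matrix(sample, db, reference)
        assert matrix.log_values[0, 0] == matrix.log_values[0, 1] == 0.0

    def test_n_bases_carry_no_information(self):
        reference, db = self._db()
        frag = make_fragment("r1", 10, "N", q=30.0)
        sample = make_sample([frag], genome_length=50, reference_id="r")
        matrix = consistency_matrix(sample, db, reference)
        assert not matrix.log_values.any()

    def test_reference_db_mismatch_rejected(self):
        reference, db = self._db()
        wrong = "T" + reference[1:]
        bad = "T" * 50
        with pytest.raises(ValueError, match="definition expects"):
            consistency_matrix(
                make_sample([], genome_length=50, reference_id="r"), db, bad
            )
        with pytest.raises(ValueError, match="genome_length"):
            consistency_matrix(
                make_sample([], genome_length=50, reference_id="r"), db, reference + "A"
            )


class TestInitProportions:
    def test_single_haplotype(self):
        assert init_proportions(1, EMConfig()) == pytest.approx([1.0])

    @pytest.mark.parametrize("n,seed", [(2, 0), (5, 1), (20, 7)])
    def test_simplex_and_positive(self, n, seed):
        p = init_proportions(n, EMConfig(seed=seed))
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).all()

    def test_seed_determinism(self):
        a = init_proportions(4, EMConfig(seed=5))
        b = init_proportions(4, EMConfig(seed=5))
        assert np.array_equal(a, b)


class TestRunEM:
    def test_forced_fixed_point(self):
        # 60 reads only consistent with h1, 40 only with h2
        strong, weak = 0.0, -50.0
        L = np.vstack(
            [np.tile([strong, weak], (60, 1)), np.tile([weak, strong], (40, 1))]
        )
        matrix = ConsistencyMatrix(L, tuple(f"r{i}" for i in range(100)), ("h1", "h2"))
        for seed in (0, 1, 2):
            est = run_em(matrix, init_proportions(2, EMConfig(seed=seed)), EMConfig())
            assert est.proportions == pytest.approx([0.6, 0.4], abs=1e-6)

    def test_dominated_haplotype_vanishes(self):
        rng = np.random.default_rng(0)
        L = random_instance(rng, 50, 2)
        L = np.column_stack([L, L.min(axis=1) - 5.0])  # third strictly dominated
        matrix = ConsistencyMatrix(L, tuple(f"r{i}" for i in range(50)), ("a", "b", "c"))
        config = EMConfig(seed=1, tol=1e-10, max_iter=5000)
        est = run_em(matrix, init_proportions(3, config), config)
        assert est.proportions[2] < config.min_prop

    def test_trace_non_decreasing_across_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n_reads = int(rng.integers(5, 60))
            n_hap = int(rng.integers(2, 6))
            L = random_instance(rng, n_reads, n_hap)
            matrix = ConsistencyMatrix(
                L, tuple(f"r{i}" for i in range(n_reads)), tuple(str(h) for h in range(n_hap))
            )
            config = EMConfig(seed=int(rng.integers(1000)))
            est = run_em(matrix, init_proportions(n_hap, config), config)
            assert np.all(np.diff(est.loglik_trace) >= -1e-9)
            assert est.proportions.sum() == pytest.approx(1.0, abs=1e-9)
            assert est.responsibilities.sum(axis=1) == pytest.approx(1.0)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(2024)
        L = random_instance(rng, 10, 2)
        matrix = ConsistencyMatrix(L, tuple(f"r{i}" for i in range(10)), ("a", "b"))
        config = EMConfig(seed=0, tol=1e-12, max_iter=20000)
        est = run_em(matrix, init_proportions(2, config), config)
        oracle_ll, oracle_p = grid_search_max_loglik(L)
        assert est.loglik_trace[-1] >= oracle_ll - 1e-6
        assert np.abs(est.proportions - oracle_p).max() <= 0.01

    def test_empty_reads_rejected(self):
        matrix = ConsistencyMatrix(np.zeros((0, 2)), (), ("a", "b"))
        with pytest.raises(ValueError, match="empty read set"):
            run_em(matrix, np.array([0.5, 0.5]), EMConfig())


class TestFilterContributors:
    def _estimate_and_matrix(self, L, config):
        matrix = ConsistencyMatrix(
            L,
            tuple(f"r{i}" for i in range(L.shape[0])),
            tuple(f"h{j}" for j in range(L.shape[1])),
        )
        est = run_em(matrix, init_proportions(L.shape[1], config), config)
        return est, matrix

    def test_proportion_floor(self):
        strong, weak = 0.0, -50.0
        L = np.vstack(
            [np.tile([strong, weak], (199, 1)), np.tile([weak, strong], (1, 1))]
        )
        config = EMConfig(seed=0, min_reads=1)
        est, matrix = self._estimate_and_matrix(L, config)
        assert est.proportions[1] < 0.01
        assert filter_contributors(est, matrix, config) == ["h0"]

    def test_read_support_requirement(self):
        strong, weak = 0.0, -50.0
        # h1 backed by a single read at ~10% proportion would pass min_prop
        L = np.vstack([np.tile([strong, weak], (9, 1)), [[weak, strong]]])
        config = EMConfig(seed=0, min_reads=2)
        est, matrix = self._estimate_and_matrix(L, config)
        assert filter_contributors(est, matrix, config) == ["h0"]
        relaxed = EMConfig(seed=0, low_coverage_mode=True)
        assert filter_contributors(est, matrix, relaxed) == ["h0", "h1"]

    def test_never_empty(self):
        L = np.zeros((3, 2))  # totally uninformative
        config = EMConfig(seed=0, min_prop=0.9)  # nothing can pass 0.9
        est, matrix = self._estimate_and_matrix(L, config)
        retained = filter_contributors(est, matrix, config)
        assert len(retained) == 1


class TestDeconvolve:
    def test_single_haplotype_sample(self, tmp_path):
        reference, db = simulate_phylotree(3, 5, 1000, seed=11)
        sam = tmp_path / "single.sam"
        simulate_mixture_reads(
            reference, db, [1.0, 0.0, 0.0], coverage=30, read_length=100,
            error_rate=0.0, seed=12, out_sam=sam,
        )
        sample = read_sam(sam, db.reference_id, db.genome_length)
        est = deconvolve(sample, db, reference, EMConfig(seed=13))
        assert est.proportion_of(db.names[0]) >= 0.99

    def test_three_way_mixture_recovery(self, tmp_path):
        reference, db = simulate_phylotree(3, 5, 2000, seed=21)
        truth_props = [0.70, 0.25, 0.05]
        sam = tmp_path / "mix.sam"
        simulate_mixture_reads(
            reference, db, truth_props, coverage=200, read_length=150,
            error_rate=0.005, seed=22, out_sam=sam,
        )
        sample = read_sam(sam, db.reference_id, db.genome_length)
        est = deconvolve(sample, db, reference, EMConfig(seed=23))
        for name, expected in zip(db.names, truth_props):
            assert est.proportion_of(name) == pytest.approx(expected, abs=0.03)

    def test_database_permutation_invariance(self, tmp_path):
        reference, db = simulate_phylotree(4, 4, 1000, seed=31)
        sam = tmp_path / "perm.sam"
        simulate_mixture_reads(
            reference, db, [0.5, 0.3, 0.2, 0.0], coverage=60, read_length=100,
            error_rate=0.005, seed=32, out_sam=sam,
        )
        sample = read_sam(sam, db.reference_id, db.genome_length)
        permuted = PhyloTreeDB(
            reference_id=db.reference_id,
            genome_length=db.genome_length,
            haplotypes={n: db.haplotypes[n] for n in reversed(db.names)},
            haplogroup_labels=db.haplogroup_labels,
        )
        config = EMConfig(seed=33)
        a = deconvolve(sample, db, reference, config).as_dict()
        b = deconvolve(sample, permuted, reference, config).as_dict()
        for name in db.names:
            assert a[name] == pytest.approx(b[name], abs=1e-3)

    def test_non_identifiable_pair_sum_is_stable(self, tmp_path):
        # two haplotypes with identical variant sets: only their SUM is defined
        reference, db3 = simulate_phylotree(2, 4, 800, seed=41)
        twin = db3.haplotypes["S1a"]
        db = PhyloTreeDB(
            reference_id=db3.reference_id,
            genome_length=db3.genome_length,
            haplotypes={
                "S1a": twin,
                "S1b": HaplotypeDefinition("S1b", twin.variants),
                "S2a": db3.haplotypes["S2a"],
            },
            haplogroup_labels=("S1", "S2"),
        )
        simulate_mixture_reads(
            reference, db, {"S1a": 0.6, "S1b": 0.0, "S2a": 0.4}, coverage=80,
            read_length=100, error_rate=0.005, seed=42, out_sam=tmp_path / "twin.sam",
        )
        sample = read_sam(tmp_path / "twin.sam", db.reference_id, db.genome_length)
        sums = []
        for seed in (1, 2, 3, 4):
            est = deconvolve(sample, db, reference, EMConfig(seed=seed))
            sums.append(est.proportion_of("S1a") + est.proportion_of("S1b"))
        assert max(sums) - min(sums) <= 0.02

    def test_deterministic_under_seed(self, tmp_path):
        reference, db = simulate_phylotree(3, 4, 600, seed=51)
        sam = tmp_path / "det.sam"
        simulate_mixture_reads(
            reference, db, [0.6, 0.3, 0.1], coverage=40, read_length=100,
            error_rate=0.005, seed=52, out_sam=sam,
        )
        sample = read_sam(sam, db.reference_id, db.genome_length)
        a = deconvolve(sample, db, reference, EMConfig(seed=9))
        b = deconvolve(sample, db, reference, EMConfig(seed=9))
        assert np.array_equal(a.proportions, b.proportions)
        assert a.contributors == b.contributors


class TestAggregate:
    def test_prefix_sum(self, toy_db):
        comp = aggregate_haplogroups({"H1a": 0.3, "H2": 0.2, "U5a": 0.5}, toy_db)
        assert comp.fractions == pytest.approx({"H": 0.5, "U5": 0.5})

    def test_mass_conservation(self, toy_db):
        comp = aggregate_haplogroups({"H1a": 0.25, "Z3": 0.75}, toy_db)
        assert comp.total == pytest.approx(1.0)
        assert comp.fractions["other"] == pytest.approx(0.75)

    def test_unmatched_goes_to_other(self, toy_db):
        comp = aggregate_haplogroups({"Z3": 1.0}, toy_db)
        assert comp.fractions == {"other": 1.0}


class TestMixtureEMEstimator:
    def test_sklearn_contract(self):
        est = MixtureEM(alpha=2.0, seed=4)
        cloned = clone(est)
        assert cloned.get_params()["alpha"] == 2.0
        rng = np.random.default_rng(0)
        L = random_instance(rng, 40, 3)
        est.fit(L)
        assert est.proportions_.shape == (3,)
        assert est.proportions_.sum() == pytest.approx(1.0)
        assert est.responsibilities_.shape == (40, 3)
        assert np.all(np.diff(est.loglik_trace_) >= -1e-9)

    def test_predict_proba_rows_normalized(self):
        rng = np.random.default_rng(1)
        L = random_instance(rng, 30, 4)
        est = MixtureEM(seed=0).fit(L)
        gamma = est.predict_proba(L)
        assert gamma.sum(axis=1) == pytest.approx(np.ones(30))
        assert est.predict(L).shape == (30,)

    def test_matches_functional_api(self, tmp_path):
        reference, db = simulate_phylotree(3, 4, 600, seed=61)
        sam = tmp_path / "est.sam"
        simulate_mixture_reads(
            reference, db, [0.6, 0.3, 0.1], coverage=40, read_length=100,
            error_rate=0.005, seed=62, out_sam=sam,
        )
        sample = read_sam(sam, db.reference_id, db.genome_length)
        matrix = consistency_matrix(sample, db, reference)
        functional = deconvolve(sample, db, reference, EMConfig(seed=7))
        estimator = MixtureEM(seed=7).fit(matrix.log_values)
        assert estimator.proportions_ == pytest.approx(functional.proportions)

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="empty read set"):
            MixtureEM().fit(np.zeros((0, 2)))
        with pytest.raises(ValueError, match="non-finite"):
            MixtureEM().fit(np.array([[0.0, -np.inf]]))
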