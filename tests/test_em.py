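"""EM engine: oracle equivalence, monotonicity, doublets, assignment."""

import warnings

import numpy as np
import pytest
import scipy.sparse as sp

import poolsplit as ps
from poolsplit.allele_counter import AlleleCountMatrices
from poolsplit.em import CellAssignment, label_cells
from poolsplit.model_init import AlleleFractionModel

from oracles import (
    brute_log_likelihood,
    brute_m_step,
    brute_posterior,
)


def _matrices(ref, alt):
    ref, alt = np.atleast_2d(ref), np.atleast_2d(alt)
    return AlleleCountMatrices(
        sp.csr_matrix(ref), sp.csr_matrix(alt),
        [f"chr1:{i + 1}" for i in range(ref.shape[0])],
        [f"BC{j}" for j in range(ref.shape[1])])


def _random_instance(rng, n_snvs, n_cells, k):
    alt = rng.integers(0, 4, size=(n_snvs, n_cells))
    ref = rng.integers(0, 4, size=(n_snvs, n_cells))
    p_alt = rng.uniform(0.05, 0.95, size=(n_snvs, k))
    w = rng.dirichlet(np.ones(k))
    return _matrices(ref, alt), AlleleFractionModel(p_alt, w)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_e_step_m_step_likelihood_match_brute_force(self, seed):
        """Vectorized log-space EM equals naive raw-product evaluation on
        tiny instances (<=3 SNVs x <=3 cells x <=2 clusters) to 1e-10."""
        rng = np.random.default_rng(seed)
        n_snvs = int(rng.integers(1, 4))
        n_cells = int(rng.integers(1, 4))
        k = int(rng.integers(1, 3))
        m, model = _random_instance(rng, n_snvs, n_cells, k)
        alt = np.asarray(m.alt.todense())
        ref = np.asarray(m.ref.todense())

        _, post = ps.e_step(model, m)
        np.testing.assert_allclose(
            post, brute_posterior(model.p_alt, alt, ref), atol=1e-10)

        new = ps.m_step(m, post, model.pseudo_alt, model.pseudo_total)
        bp, bw = brute_m_step(alt, ref, post, model.pseudo_alt,
                              model.pseudo_total)
        np.testing.assert_allclose(new.p_alt, bp, atol=1e-10)
        np.testing.assert_allclose(new.weights, bw, atol=1e-10)

        ll = ps.model_log_likelihood(model, m)
        assert ll == pytest.approx(
            brute_log_likelihood(model.p_alt, model.weights, alt, ref),
            abs=1e-10)

    def test_single_cluster_posterior_is_one(self):
        m, model = _random_instance(np.random.default_rng(0), 3, 3, 1)
        _, post = ps.e_step(model, m)
        np.testing.assert_allclose(post, 1.0)

    def test_empty_cell_posterior_uniform(self):
        m = _matrices(np.zeros((2, 1)), np.zeros((2, 1)))
        model = AlleleFractionModel(np.full((2, 3), 0.3), np.full(3, 1 / 3))
        _, post = ps.e_step(model, m)
        np.testing.assert_allclose(post, 1 / 3)

    def test_single_observation_likelihood(self):
        """One cell, one cluster, one SNV with N_A=1, P_A=0.5: L=log(0.5)."""
        m = _matrices(ref=[[0]], alt=[[1]])
        model = AlleleFractionModel(np.array([[0.5]]), np.array([1.0]))
        assert ps.model_log_likelihood(model, m) == pytest.approx(np.log(0.5))


class TestEmIterations:
    def test_em_objective_monotone(self, small_pool):
        """The fitted objective (log-likelihood plus the pseudo-count
        prior, i.e. the quantity the MAP M-step ascends) never decreases
        across iterations on simulated data."""
        _, matrices, _ = small_pool
        result = ps.run_restarts(matrices, 2, n_restarts=1,
                                 rng=np.random.default_rng(1))
        diffs = np.diff(result.map_history)
        assert (diffs >= -1e-8).all()
        assert result.converged
        # the raw likelihood tracks it up to the (small) prior pull
        raw = np.diff(result.ll_history)
        assert (raw >= -1e-4 * np.abs(np.asarray(result.ll_history[:-1]))).all()

    def test_posterior_rows_normalized(self, small_pool):
        _, matrices, _ = small_pool
        rng = np.random.default_rng(2)
        m, model = _random_instance(rng, 5, 10, 3)
        _, post = ps.e_step(model, m)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_infinite_tolerance_single_iteration(self):
        m, model = _random_instance(np.random.default_rng(3), 4, 5, 2)
        result = ps.run_em(m, model, tol=np.inf)
        assert result.n_iter == 1

    def test_permutation_equivariance(self):
        """Permuting cluster columns of the model permutes all outputs."""
        m, model = _random_instance(np.random.default_rng(4), 4, 6, 3)
        perm = [2, 0, 1]
        permuted = AlleleFractionModel(model.p_alt[:, perm],
                                       model.weights[perm])
        _, post = ps.e_step(model, m)
        _, post_p = ps.e_step(permuted, m)
        np.testing.assert_allclose(post_p, post[:, perm], atol=1e-12)
        r1 = ps.run_em(m, model, tol=np.inf)
        r2 = ps.run_em(m, permuted, tol=np.inf)
        np.testing.assert_allclose(r2.model.p_alt, r1.model.p_alt[:, perm],
                                   atol=1e-12)

    def test_parameter_recovery_from_generative_model(self):
        """Counts drawn exactly from a 2-cluster model: the fitted allele
        fractions correlate > 0.99 with the truth up to permutation."""
        rng = np.random.default_rng(12)
        n_snvs, n_cells = 80, 120
        p_truth = rng.uniform(0.05, 0.95, size=(n_snvs, 2))
        member = rng.integers(0, 2, size=n_cells)
        depth = rng.poisson(6, size=(n_snvs, n_cells)) + 1
        alt = rng.binomial(depth, p_truth[:, member])
        ref = depth - alt
        m = _matrices(ref, alt)
        fit = ps.run_restarts(m, 2, n_restarts=5,
                              rng=np.random.default_rng(5),
                              extra_doublet_cluster=False,
                              target_density=0.5)
        corr = [
            np.corrcoef(fit.model.p_alt[:, list(perm)].ravel(),
                        p_truth.ravel())[0, 1]
            for perm in ([0, 1], [1, 0])
        ]
        assert max(corr) > 0.99


class TestRestarts:
    def test_deterministic_given_seed(self, small_pool):
        _, matrices, _ = small_pool
        a = ps.run_restarts(matrices, 2, n_restarts=2,
                            rng=np.random.default_rng(7))
        b = ps.run_restarts(matrices, 2, n_restarts=2,
                            rng=np.random.default_rng(7))
        assert a.log_likelihood == b.log_likelihood
        np.testing.assert_array_equal(a.posterior, b.posterior)

    def test_more_restarts_never_worse(self, small_pool):
        _, matrices, _ = small_pool
        one = ps.run_restarts(matrices, 2, n_restarts=1,
                              rng=np.random.default_rng(8))
        five = ps.run_restarts(matrices, 2, n_restarts=5,
                               rng=np.random.default_rng(8))
        assert five.log_likelihood >= one.log_likelihood - 1e-9


class TestAssignCells:
    @pytest.mark.parametrize("posterior,expected", [
        ((0.995, 0.005), 0),
        ((0.99, 0.01), -1),   # strict: exactly at threshold is unassigned
        ((0.5, 0.5), -1),
    ])
    def test_threshold_is_strict(self, posterior, expected):
        labels = ps.assign_cells(np.array([posterior]), threshold=0.99)
        assert labels[0] == expected


class TestDoubletHandling:
    def _assignment(self, posterior, matrices, doublet_cluster=None):
        k = posterior.shape[1]
        model = AlleleFractionModel(np.full((matrices.n_snvs, k), 0.5),
                                    np.full(k, 1 / k))
        return CellAssignment(
            barcodes=list(matrices.barcodes), posterior=posterior,
            model=model, log_likelihood=0.0, converged=True, n_iter=1,
            doublet_cluster=doublet_cluster)

    def test_average_cluster_selected(self):
        """A cluster whose allele fractions average the other two explains
        foreign cells best and is designated the doublet cluster."""
        rng = np.random.default_rng(0)
        n_snvs, per = 60, 40
        p0 = np.full(n_snvs, 0.05)
        p1 = np.full(n_snvs, 0.95)
        depth = 8
        alt = np.concatenate([
            rng.binomial(depth, p0, size=(per, n_snvs)),
            rng.binomial(depth, p1, size=(per, n_snvs)),
        ]).T
        ref = depth - alt
        m = _matrices(ref, alt)
        model = AlleleFractionModel(
            np.column_stack([p0 * 0.9 + 0.05, p1 * 0.9 + 0.05,
                             (p0 + p1) / 2 * 0.9 + 0.05]),
            np.array([0.45, 0.45, 0.10]))
        _, post = ps.e_step(model, m)
        assignment = self._assignment(post, m)
        assignment.model = model
        assert ps.identify_doublet_cluster(assignment, m) == 2

    def test_identical_clusters_tie_to_lowest_index(self):
        m = _matrices(np.full((3, 2), 2), np.full((3, 2), 2))
        post = np.array([[0.6, 0.4], [0.4, 0.6]])
        assignment = self._assignment(post, m)
        with pytest.warns(UserWarning, match="tie"):
            assert ps.identify_doublet_cluster(assignment, m) == 0

    def test_doublet_expectation_topup_by_depth(self):
        """10 cells, 1 detected doublet, fraction 0.3: the 2 deepest
        singlets are relabelled DBL."""
        depths = np.array([5, 50, 7, 90, 9, 11, 13, 15, 17, 19])
        alt = np.zeros((1, 10), dtype=int)
        m = _matrices(depths[None, :], alt)
        post = np.zeros((10, 2))
        post[:, 0] = 1.0
        post[0, :] = [0.0, 1.0]  # cell 0 sits in the doublet cluster
        a = self._assignment(post, m, doublet_cluster=1)
        a = label_cells(a, threshold=0.99)
        assert a.labels.count("DBL") == 1
        a = ps.apply_doublet_expectation(a, m, expected_doublet_fraction=0.3)
        assert a.labels.count("DBL") == 3
        assert a.labels[3] == "DBL" and a.labels[1] == "DBL"  # depths 90, 50

    def test_expectation_met_or_zero_changes_nothing(self):
        m = _matrices(np.ones((1, 4)), np.zeros((1, 4)))
        post = np.eye(2)[[0, 0, 0, 1]] * 0.998 + 0.001
        post = post / post.sum(axis=1, keepdims=True)
        a = self._assignment(post, m, doublet_cluster=1)
        a = label_cells(a, threshold=0.99)
        before = list(a.labels)
        assert ps.apply_doublet_expectation(a, m, 0.0).labels == before
        assert ps.apply_doublet_expectation(a, m, 0.25).labels == before

    def test_invalid_fraction_rejected(self):
        m = _matrices(np.ones((1, 2)), np.zeros((1, 2)))
        post = np.array([[1.0, 0.0], [0.0, 1.0]])
        a = self._assignment(post, m, doublet_cluster=1)
        a = label_cells(a)
        with pytest.raises(ps.errors.PoolsplitError):
            ps.apply_doublet_expectation(a, m, 1.5)


def test_nonconvergence_warns():
    rng = np.random.default_rng(9)
    alt = rng.integers(0, 6, size=(20, 30))
    ref = rng.integers(0, 6, size=(20, 30))
    m = _matrices(ref, alt)
    model = AlleleFractionModel(rng.uniform(0.2, 0.8, (20, 2)),
                                np.array([0.5, 0.5]))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = ps.run_em(m, model, tol=0.0, max_iter=3)
    assert not result.converged
    assert any("converge" in str(w.message) for w in caught)
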