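import warnings

import numpy as np
import pytest
import scipy.sparse.csgraph as csgraph

from neuroroi.headmodel import simulate_eeg, simulate_sources
from neuroroi.inverse import (
    build_patch_dictionary, loreta_solve, msp_solve, reml_optimize,
    solve_regularized,
)
from neuroroi.roi import source_energy


def _brute_minimizer(X, M, Q_J, Q_eps, lam):
    """Normal-equations minimizer of the penalized Mahalanobis objective."""
    return np.linalg.solve(
        M.T @ np.linalg.inv(Q_eps) @ M + lam * np.linalg.inv(Q_J),
        M.T @ np.linalg.inv(Q_eps) @ X,
    )


def _random_instance(rng):
    C = int(rng.integers(3, 9))
    D = int(rng.integers(4, 17))
    M = rng.standard_normal((C, D))
    A = rng.standard_normal((D, D))
    B = rng.standard_normal((C, C))
    return (
        rng.standard_normal((C, 5)), M,
        A @ A.T + 0.5 * np.eye(D), B @ B.T + 0.5 * np.eye(C),
        float(10 ** rng.uniform(-2, 1)),
    )


class TestSolveRegularized:
    def test_zero_data_gives_zero_solution(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((4, 9))
        sol = solve_regularized(np.zeros((4, 7)), M, np.eye(9), np.eye(4), 1.0)
        assert not sol.J_hat.any()

    def test_noiseless_limit_inverts_square_system(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        X = rng.standard_normal((4, 3))
        sol = solve_regularized(X, M, np.eye(4), 1e-12 * np.eye(4), 1.0)
        assert np.abs(sol.J_hat - np.linalg.solve(M, X)).max() < 1e-4

    def test_matches_brute_force_minimizer(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            X, M, Q_J, Q_eps, lam = _random_instance(rng)
            J = solve_regularized(X, M, Q_J, Q_eps, lam).J_hat
            assert np.abs(J - _brute_minimizer(X, M, Q_J, Q_eps, lam)).max() < 1e-8

    def test_woodbury_consistency(self):
        # the C x C sensor-space form must equal the D x D source-space form
        rng = np.random.default_rng(3)
        X, M, Q_J, Q_eps, lam = _random_instance(rng)
        J_sensor = solve_regularized(X, M, Q_J, Q_eps, lam).J_hat
        J_source = _brute_minimizer(X, M, Q_J, Q_eps, lam)
        assert np.abs(J_sensor - J_source).max() < 1e-8

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            solve_regularized(np.zeros((3, 2)), np.zeros((4, 5)),
                              np.eye(5), np.eye(4), 1.0)

    def test_nonpositive_lambda_raises(self):
        with pytest.raises(ValueError):
            solve_regularized(np.zeros((2, 2)), np.eye(2), np.eye(2),
                              np.eye(2), 0.0)


class TestLoreta:
    def test_shrinkage_with_growing_lambda(self, small_head):
        J, _ = simulate_sources(small_head.mesh, small_head.Q_G, 1, 128, 1.0, seed=0)
        X = simulate_eeg(small_head.leadfield, J, snr_db=10.0, seed=0).X
        norms = [np.linalg.norm(
            loreta_solve(X, small_head.leadfield, small_head.Q_G, lam).J_hat)
            for lam in (1.0, 10.0, 100.0, 1000.0)]
        assert np.all(np.diff(norms) < 0)

    def test_localizes_single_patch(self, small_head):
        adj = small_head.mesh.vertex_adjacency()
        hits = 0
        for seed in range(6):
            J, centers = simulate_sources(small_head.mesh, small_head.Q_G,
                                          1, 128, 2.0, seed=seed)
            X = simulate_eeg(small_head.leadfield, J, snr_db=10.0, seed=seed).X
            sol = loreta_solve(X, small_head.leadfield, small_head.Q_G, lam=1.0)
            peak = int(np.argmax(source_energy(sol.J_hat).e_bar))
            d = csgraph.shortest_path(adj, unweighted=True, indices=peak)[centers[0]]
            hits += d <= 2
        assert hits >= 5


class TestPatchDictionary:
    def test_exhaustive_selection(self, mesh1):
        from neuroroi.headmodel import graph_laplacian, greens_function
        Q = greens_function(graph_laplacian(mesh1), 0.6)
        comps = build_patch_dictionary(Q, mesh1.n_vertices, mesh=mesh1)
        assert sorted(c.index for c in comps) == list(range(mesh1.n_vertices))

    def test_two_centers_at_maximal_distance(self, mesh1):
        from neuroroi.headmodel import graph_laplacian, greens_function
        Q = greens_function(graph_laplacian(mesh1), 0.6)
        comps = build_patch_dictionary(Q, 2, mesh=mesh1)
        d = csgraph.shortest_path(mesh1.vertex_adjacency(), unweighted=True)
        i, j = comps[0].index, comps[1].index
        assert d[i, j] == d.max()

    def test_support_coverage(self, mesh2):
        from neuroroi.headmodel import graph_laplacian, greens_function
        Q = greens_function(graph_laplacian(mesh2), 0.6)
        comps = build_patch_dictionary(Q, mesh2.n_vertices // 4, mesh=mesh2)
        covered = np.zeros(mesh2.n_vertices, dtype=bool)
        for c in comps:
            covered |= c.q > 1e-3 * c.q.max()
        assert covered.mean() >= 0.95

    def test_oversized_dictionary_raises(self, mesh1):
        from neuroroi.headmodel import graph_laplacian, greens_function
        Q = greens_function(graph_laplacian(mesh1), 0.6)
        with pytest.raises(ValueError):
            build_patch_dictionary(Q, mesh1.n_vertices + 1, mesh=mesh1)

    def test_components_nonnegative_with_positive_peak(self, mesh2):
        from neuroroi.headmodel import graph_laplacian, greens_function
        Q = greens_function(graph_laplacian(mesh2), 0.6)
        for c in build_patch_dictionary(Q, 16, mesh=mesh2):
            assert c.q.min() >= -1e-9
            assert c.q.max() > 0


@pytest.fixture(scope="module")
def small_dict(small_head):
    return build_patch_dictionary(small_head.Q_G, 128, mesh=small_head.mesh)


class TestRemlMsp:
    def test_objective_trace_nondecreasing(self, small_head, small_dict):
        rng = np.random.default_rng(0)
        comp = small_dict[31]
        s = 2.0 * np.sin(2 * np.pi * 10 * np.arange(256) / 128)
        J = np.outer(comp.q / comp.q.max(), s)
        X = simulate_eeg(small_head.leadfield, J, snr_db=10.0, seed=0).X
        _, trace = reml_optimize((X @ X.T) / X.shape[1], small_head.leadfield,
                                 small_dict)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8 * np.maximum(np.abs(trace[:-1]), 1.0))

    def test_generative_recovery(self, small_head, small_dict):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = int(rng.integers(len(small_dict)))
            s = 2.0 * np.sin(2 * np.pi * 10 * np.arange(512) / 128 + rng.uniform(0, 6))
            J = np.outer(small_dict[p].q / small_dict[p].q.max(), s)
            X = simulate_eeg(small_head.leadfield, J, snr_db=10.0, seed=seed).X
            hyper, _ = reml_optimize((X @ X.T) / X.shape[1],
                                     small_head.leadfield, small_dict)
            w = hyper.weights
            hits += (not hyper.pruned[p]) and w[p] / w.sum() >= 0.90
        assert hits >= 4

    def test_null_data_suppresses_sources(self, small_head, small_dict):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((32, 512))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hyper, _ = reml_optimize((X @ X.T) / X.shape[1],
                                     small_head.leadfield, small_dict)
        assert hyper.weights.sum() < 0.01 * np.exp(hyper.lambda_eps)

    def test_rejects_non_psd_covariance(self, small_head, small_dict):
        C_y = -np.eye(32)
        with pytest.raises(ValueError):
            reml_optimize(C_y, small_head.leadfield, small_dict)

    def test_msp_zero_data_gives_zero_solution(self, small_head, small_dict):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = msp_solve(np.zeros((32, 64)), small_head.leadfield, small_dict)
        assert not sol.J_hat.any()

    def test_msp_localizes_at_low_snr(self, small_head, small_dict):
        ok_loc = 0
        adj = small_head.mesh.vertex_adjacency()
        n_seeds = 5
        for seed in range(n_seeds):
            J, centers = simulate_sources(small_head.mesh, small_head.Q_G,
                                          1, 128, 2.0, seed=seed)
            X = simulate_eeg(small_head.leadfield, J, snr_db=5.0, seed=seed).X
            sol = msp_solve(X, small_head.leadfield, small_dict)
            peak = int(np.argmax(source_energy(sol.J_hat).e_bar))
            d = csgraph.shortest_path(adj, unweighted=True, indices=peak)[centers[0]]
            ok_loc += d <= 2
        assert ok_loc >= 4

    def test_msp_is_sparse_on_single_patch(self, small_head, small_dict):
        ok_sparse = 0
        n_seeds = 5
        for seed in range(n_seeds):
            J, _ = simulate_sources(small_head.mesh, small_head.Q_G,
                                    1, 128, 2.0, seed=seed)
            X = simulate_eeg(small_head.leadfield, J, snr_db=10.0, seed=seed).X
            sol = msp_solve(X, small_head.leadfield, small_dict)
            ok_sparse += len(sol.components) <= 0.05 * len(small_dict)
        assert ok_sparse >= 4

    def test_msp_two_patch_recovery(self, small_head, small_dict):
        from neuroroi.roi import select_rois
        adj = small_head.mesh.vertex_adjacency()
        # restrict sources to the sensor-covered cortex: patches under the
        # cap's rim are invisible to any inverse method
        covered = np.flatnonzero(small_head.mesh.vertices[:, 2] > 0.0)
        hits = 0
        for seed in range(5):
            J, centers = simulate_sources(small_head.mesh, small_head.Q_G,
                                          2, 128, 2.0, seed=seed,
                                          candidate_vertices=covered)
            X = simulate_eeg(small_head.leadfield, J, snr_db=5.0, seed=seed).X
            sol = msp_solve(X, small_head.leadfield, small_dict)
            lab = select_rois(source_energy(sol.J_hat), small_head.mesh,
                              rho_mm=25.0)
            d = csgraph.shortest_path(adj, unweighted=True,
                                      indices=lab.centers[:2])[:, centers]
            # each true centre matched by some selected peak within 2 edges
            hits += np.all(d.min(axis=0) <= 2)
        assert hits >= 4
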