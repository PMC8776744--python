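"""GNM core: Kirchhoff invariants, spectra, fluctuations, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays as st_arrays

from gnmcompare.errors import UndefinedCorrelationError
from gnmcompare.gnm import (
    bfactor_correlation,
    build_kirchhoff,
    cross_correlation,
    decompose,
    fluctuations,
    slow_mode_profile,
    theoretical_bfactors,
)
from gnmcompare.structures import GNMNode, NodeSet
from gnmcompare.synthetic import SyntheticSpec, make_tetramer


def nodes_from_coords(coords, bfactors=None):
    coords = np.asarray(coords, float)
    b = np.ones(len(coords)) if bfactors is None else np.asarray(bfactors)
    return NodeSet(
        [GNMNode("A", 15 + i, "CA", "calpha", tuple(map(float, c)), float(bi))
         for i, (c, bi) in enumerate(zip(coords, b))],
        "test")


def path_nodes(n, spacing=3.8):
    return nodes_from_coords(
        np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)]))


class TestKirchhoff:
    def test_single_contact_dimer(self):
        K = build_kirchhoff(nodes_from_coords([[0, 0, 0], [5, 0, 0]]), 7.3, 1.0)
        assert np.array_equal(K.matrix, [[1, -1], [-1, 1]])

    def test_no_contact_beyond_cutoff(self):
        K = build_kirchhoff(nodes_from_coords([[0, 0, 0], [8, 0, 0]]), 7.3, 1.0)
        assert np.array_equal(K.matrix, np.zeros((2, 2)))
        assert decompose(K).zero_mode_count == 2

    def test_collinear_chain_gives_path_laplacian(self):
        # next-nearest spacing 7.6 Å > 7.3 Å cutoff -> tridiagonal
        K = build_kirchhoff(path_nodes(6), 7.3, 1.0)
        expected = (np.diag([1, 2, 2, 2, 2, 1])
                    - np.diag(np.ones(5), 1) - np.diag(np.ones(5), -1))
        assert np.array_equal(K.matrix, expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariants_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        nodes = nodes_from_coords(rng.uniform(0, 20, (30, 3)))
        K = build_kirchhoff(nodes, 7.3, 1.0)
        K.validate()
        w = np.linalg.eigvalsh(K.matrix)
        assert w[0] > -1e-10  # positive semidefinite

    @given(
        coords=st_arrays(
            np.float64, (12, 3),
            elements=st.floats(0.0, 25.0, allow_nan=False)),
        gamma=st.floats(0.1, 10.0),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_laplacian_invariants_hold_for_any_cloud(self, coords, gamma):
        K = build_kirchhoff(nodes_from_coords(coords), 7.3, gamma)
        K.validate()
        w = np.linalg.eigvalsh(K.matrix)
        assert w[0] > -1e-8 * max(w[-1], 1.0)

    def test_rejects_fewer_than_two_nodes(self):
        with pytest.raises(ValueError):
            build_kirchhoff(nodes_from_coords([[0, 0, 0]]))

    def test_rejects_nonfinite_coordinates(self):
        with pytest.raises(ValueError, match="A:16"):
            build_kirchhoff(nodes_from_coords([[0, 0, 0], [np.nan, 0, 0]]))


class TestDecomposition:
    @pytest.mark.parametrize("n", [4, 10, 25, 50])
    def test_path_graph_closed_form_eigenvalues(self, n):
        # path-graph Laplacian spectrum: 4 sin^2(k pi / 2N), k = 0..N-1
        modes = decompose(build_kirchhoff(path_nodes(n), 7.3, 1.0))
        expected = 4.0 * np.sin(np.arange(n) * np.pi / (2 * n)) ** 2
        assert np.abs(modes.eigenvalues - expected).max() < 1e-8

    def test_connected_graph_has_one_zero_mode(self, tetramer):
        st, _ = tetramer
        from gnmcompare.structures import select_gnm_nodes

        modes = decompose(build_kirchhoff(select_gnm_nodes(st, 15, 135)))
        assert modes.zero_mode_count == 1
        assert modes.n_nonzero == modes.n - 1

    def test_two_disconnected_dimers_two_zero_modes(self):
        nodes = nodes_from_coords(
            [[0, 0, 0], [5, 0, 0], [100, 0, 0], [105, 0, 0]])
        assert decompose(build_kirchhoff(nodes)).zero_mode_count == 2

    def test_eigenvectors_orthonormal(self):
        modes = decompose(build_kirchhoff(path_nodes(20)))
        gram = modes.eigenvectors.T @ modes.eigenvectors
        assert np.abs(gram - np.eye(20)).max() < 1e-8

    def test_sign_convention_is_deterministic(self):
        m1 = decompose(build_kirchhoff(path_nodes(15)))
        m2 = decompose(build_kirchhoff(path_nodes(15)))
        assert np.array_equal(m1.eigenvectors, m2.eigenvectors)
        piv = np.argmax(np.abs(m1.eigenvectors), axis=0)
        assert (m1.eigenvectors[piv, np.arange(15)] > 0).all()


class TestFluctuations:
    def test_all_modes_equal_pseudoinverse(self):
        for n in (5, 20, 50):
            K = build_kirchhoff(path_nodes(n))
            fl = fluctuations(decompose(K))
            pinv = np.linalg.pinv(K.matrix, hermitian=True, rcond=1e-8)
            assert np.abs(fl.values - pinv).max() < 1e-8

    def test_row_sums_zero_for_connected_graph(self, tetramer):
        st, _ = tetramer
        from gnmcompare.structures import select_gnm_nodes

        fl = fluctuations(decompose(build_kirchhoff(
            select_gnm_nodes(st, 15, 135))))
        assert np.abs(fl.values.sum(axis=1)).max() < 1e-8

    def test_slowest_mode_profile_matches_closed_form(self):
        n = 12
        modes = decompose(build_kirchhoff(path_nodes(n)))
        fl = fluctuations(modes, n_slowest=1)
        # first nontrivial path eigenvector: cos((i+1/2) pi / n)
        u = np.cos((np.arange(n) + 0.5) * np.pi / n)
        u /= np.linalg.norm(u)
        lam = 4 * np.sin(np.pi / (2 * n)) ** 2
        assert np.allclose(np.diag(fl.values), u ** 2 / lam, atol=1e-8)
        assert fl.msf[0] > fl.msf[n // 2]  # chain ends exceed chain centre

    def test_zero_mode_subset_rejected(self):
        modes = decompose(build_kirchhoff(path_nodes(6)))
        with pytest.raises(ValueError):
            fluctuations(modes, mode_indices=[0, 1])

    def test_gamma_scale_invariance(self):
        nodes = path_nodes(10)
        rng = np.random.default_rng(0)
        b = rng.uniform(5, 30, 10)
        results = []
        for gamma in (1.0, 3.5):
            fl = fluctuations(decompose(build_kirchhoff(nodes, 7.3, gamma)))
            cc = cross_correlation(fl)
            r = bfactor_correlation(theoretical_bfactors(fl), b)
            results.append((cc.values.copy(), r, fl.msf.copy()))
        assert np.abs(results[0][0] - results[1][0]).max() < 1e-8
        assert results[0][1] == pytest.approx(results[1][1], abs=1e-12)
        assert np.allclose(results[0][2], 3.5 * results[1][2])


class TestCrossCorrelation:
    def test_unit_diagonal_and_bounds_on_fuzzed_assemblies(self):
        for seed in range(12):
            st, _ = make_tetramer(SyntheticSpec(seed=100 + seed, nodes_per_chain=8,
                                                interchain_contacts=4))
            from gnmcompare.structures import select_gnm_nodes

            cc = cross_correlation(fluctuations(decompose(
                build_kirchhoff(select_gnm_nodes(st, 15, 135)))))
            assert np.allclose(np.diag(cc.values), 1.0)
            assert np.abs(cc.values).max() <= 1.0 + 1e-12

    def test_two_node_contact_fully_anticorrelated(self):
        cc = cross_correlation(fluctuations(decompose(build_kirchhoff(
            nodes_from_coords([[0, 0, 0], [5, 0, 0]])))))
        assert cc.values[0, 1] == pytest.approx(-1.0)

    def test_section_slicing(self, tetramer):
        st, _ = tetramer
        from gnmcompare.structures import select_gnm_nodes

        nodes = select_gnm_nodes(st, 15, 135)
        cc = cross_correlation(fluctuations(decompose(build_kirchhoff(nodes))))
        sub, rnum, cnum = cc.section("A", "B")
        n_a = len(nodes.indices(chain="A", kind="calpha"))
        n_b = len(nodes.indices(chain="B", kind="calpha"))
        assert sub.shape == (n_a, n_b)
        assert rnum[0] == 15 and cnum[0] == 15


class TestBfactorValidation:
    def test_affine_invariance(self):
        t = np.array([1.0, 2.0, 3.0, 5.0])
        assert bfactor_correlation(t, 2.5 * t + 7) == pytest.approx(1.0)
        assert bfactor_correlation(t, -t) == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            bfactor_correlation(np.arange(5.0), np.ones(5))

    def test_parameter_recovery_under_noise(self):
        """B = a*MSF + noise recovers r >= 0.9 at sigma <= 10% of signal."""
        ok = 0
        for seed in range(20):
            st, gt = make_tetramer(SyntheticSpec(seed=200 + seed, nodes_per_chain=12,
                                        interchain_contacts=4))
            from gnmcompare.structures import select_gnm_nodes

            nodes = select_gnm_nodes(st, 15, 135)
            theo = theoretical_bfactors(fluctuations(decompose(
                build_kirchhoff(nodes))))
            rng = np.random.default_rng(seed)
            a = 30.0
            sigma = 0.1 * a * theo.mean()
            exp = a * theo + rng.normal(0, sigma, len(theo))
            ok += bfactor_correlation(theo, exp) >= 0.9
        assert ok == 20

    def test_noiseless_synthetic_bfactors_give_r_one(self):
        st, _ = make_tetramer(SyntheticSpec(seed=5, bfactor_noise=0.0))
        from gnmcompare.structures import select_gnm_nodes

        nodes = select_gnm_nodes(st, 15, 135)
        theo = theoretical_bfactors(fluctuations(decompose(
            build_kirchhoff(nodes))))
        # B-factors stored at 2-decimal PDB precision
        assert bfactor_correlation(theo, nodes.bfactors) > 0.9999


class TestSlowModeProfile:
    def test_all_modes_equals_theoretical_bfactors(self):
        modes = decompose(build_kirchhoff(path_nodes(15)))
        full = slow_mode_profile(modes, modes.n_nonzero)
        theo = theoretical_bfactors(fluctuations(modes))
        assert np.allclose(full, theo, atol=1e-10)

    def test_profile_nondecreasing_in_mode_count(self):
        modes = decompose(build_kirchhoff(path_nodes(15)))
        prev = np.zeros(15)
        for k in range(1, modes.n_nonzero + 1):
            cur = slow_mode_profile(modes, k)
            assert (cur >= prev - 1e-12).all()
            prev = cur

    def test_exceeding_available_modes_raises(self):
        modes = decompose(build_kirchhoff(path_nodes(6)))
        with pytest.raises(ValueError):
            slow_mode_profile(modes, 6)

    def test_symmetric_tetramer_has_identical_chain_profiles(self):
        """Exact 222 assembly: the four chains are equivalent by symmetry."""
        st, _ = make_tetramer(SyntheticSpec(seed=9, asymmetry=0.0))
        from gnmcompare.structures import select_gnm_nodes

        nodes = select_gnm_nodes(st, 15, 135)
        modes = decompose(build_kirchhoff(nodes))
        prof = slow_mode_profile(modes, 10)
        chains = [prof[nodes.indices(chain=c, kind="calpha")] for c in "ABCD"]
        for other in chains[1:]:
            assert np.abs(chains[0] - other).max() < 1e-8
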