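import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mortsurv as ms
from mortsurv.io import AdjacencyGraph, MortalityDataset
from mortsurv.model import Components, eta_grid, icar_structure, rw1_structure

from conftest import make_posterior


class TestStructureMatrices:
    def test_rw1_n3_by_hand(self):
        np.testing.assert_array_equal(
            rw1_structure(3), [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]
        )

    @pytest.mark.parametrize("n", [2, 5, 6, 20])
    def test_rw1_rowsums_and_rank(self, n):
        r = rw1_structure(n)
        np.testing.assert_allclose(r.sum(axis=1), 0, atol=1e-12)
        assert np.linalg.matrix_rank(r) == n - 1

    def test_rw1_rejects_small_n(self):
        with pytest.raises(ValueError):
            rw1_structure(1)

    @given(st.integers(3, 12), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rw1_quadratic_form_is_squared_increments(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        assert x @ rw1_structure(n) @ x == pytest.approx(np.sum(np.diff(x) ** 2))

    def test_icar_path_by_hand(self):
        g = AdjacencyGraph(3, [[1], [0, 2], [1]])
        np.testing.assert_array_equal(
            icar_structure(g), [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]
        )

    def test_icar_2x2_lattice(self):
        lap = icar_structure(ms.make_lattice_graph(2, 2))
        np.testing.assert_array_equal(np.diag(lap), [2, 2, 2, 2])
        assert np.linalg.matrix_rank(lap) == 3

    def test_icar_two_disjoint_edges(self):
        g = AdjacencyGraph(4, [[1], [0], [3], [2]])
        assert np.linalg.matrix_rank(icar_structure(g)) == 2

    def test_rw1_equals_path_laplacian(self):
        g = AdjacencyGraph(6, [[1], [0, 2], [1, 3], [2, 4], [3, 5], [4]])
        np.testing.assert_array_equal(rw1_structure(6), icar_structure(g))


def _components(I=2, J=2, T=2, D=2, **over):
    c = Components.zeros(I, J, T, D, decile_index=np.arange(I) % D)
    for k, v in over.items():
        setattr(c, k, v)
    return c


class TestLinearPredictor:
    def test_identity_case(self):
        c = _components()
        c.a0 = -4.0
        assert ms.linear_predictor(c, 0, 1, 1) == -4.0

    def test_every_term_enters_once(self):
        # distinct powers of ten make the sum digit-decodable
        c = _components(I=2, J=2, T=2, D=2)
        c.a0 = 1.0
        c.alpha[1] = 10.0
        c.gamma[1] = 100.0
        c.zeta[1] = 1_000.0
        c.phi[1] = 10_000.0
        c.omega[1, 1] = 100_000.0
        c.delta[1, 1] = 1_000_000.0
        c.kappa[1, 1] = 10_000_000.0
        c.nu[1, 1] = 100_000_000.0
        assert ms.linear_predictor(c, 1, 1, 1) == 111_111_111.0

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(5)
        I, J, T, D = 3, 4, 5, 2
        dix = np.array([0, 1, 0])
        c = Components(
            a0=rng.normal(), alpha=rng.normal(size=J), gamma=rng.normal(size=I),
            zeta=rng.normal(size=T), phi=rng.normal(size=D),
            omega=rng.normal(size=(I, T)), delta=rng.normal(size=(I, J)),
            kappa=rng.normal(size=(J, T)), nu=rng.normal(size=(D, T)),
            decile_index=dix,
        )
        grid = eta_grid(c)
        for i in range(I):
            for j in range(J):
                for t in range(T):
                    expected = (c.a0 + c.alpha[j] + c.gamma[i] + c.zeta[t]
                                + c.phi[dix[i]] + c.omega[i, t] + c.delta[i, j]
                                + c.kappa[j, t] + c.nu[dix[i], t])
                    assert ms.linear_predictor(c, i, j, t) == pytest.approx(
                        expected, abs=1e-12)
                    assert grid[i, j, t] == pytest.approx(expected, abs=1e-12)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            ms.linear_predictor(_components(), 5, 0, 0)


def _single_cell_dataset(deaths, population):
    return MortalityDataset(
        area_ids=["A0", "A1"], age_groups=[(0, 1), (1, None)], years=[2015],
        sex="female",
        deaths=np.array([[[deaths], [0]], [[0], [0]]]),
        population=np.array([[[population], [0.0]], [[0.0], [0.0]]]),
        decile={"A0": 1, "A1": 2},
    )


class TestLogLikelihood:
    def test_zero_deaths_gives_minus_mean(self):
        data = _single_cell_dataset(0, 100.0)
        c = _components(T=1)
        c.a0 = math.log(0.01)
        assert ms.log_likelihood(c, data) == pytest.approx(-1.0, abs=1e-12)

    def test_scalar_pmf_value(self):
        data = _single_cell_dataset(2, 100.0)
        c = _components(T=1)
        c.a0 = math.log(0.02)
        expected = 2 * math.log(2) - 2 - math.log(2)
        assert ms.log_likelihood(c, data) == pytest.approx(expected, abs=1e-12)

    def test_zero_population_cells_contribute_nothing(self):
        data = _single_cell_dataset(3, 50.0)
        c = _components(T=1)
        c.a0 = math.log(0.05)
        c.gamma = np.array([0.0, 50.0])  # huge rate in the empty cells
        base = _components(T=1)
        base.a0 = math.log(0.05)
        assert ms.log_likelihood(c, data) == ms.log_likelihood(base, data)

    def test_matches_brute_force_on_synthetic(self, small_sim):
        _, data, truth, _ = small_sim
        ll = ms.log_likelihood(truth.components, data)
        brute = 0.0
        eta = truth.eta
        for i in range(data.n_areas):
            for j in range(data.n_ages):
                for t in range(data.n_years):
                    pop = data.population[i, j, t]
                    if pop > 0:
                        mu = math.exp(eta[i, j, t]) * pop
                        y = int(data.deaths[i, j, t])
                        brute += y * math.log(mu) - mu - math.lgamma(y + 1)
        assert ll == pytest.approx(brute, abs=1e-8)

    def test_nonfinite_predictor_rejected(self, small_sim):
        _, data, truth, _ = small_sim
        c = truth.components
        bad = Components(**{**c.__dict__, "a0": float("inf")})
        with pytest.raises(ValueError, match="non-finite"):
            ms.log_likelihood(bad, data)


class TestFit:
    def test_determinism_same_seed(self, small_sim):
        _, data, _, graph = small_sim
        cfg = ms.ModelConfig(n_chains=1, burn_in=50, n_iter=100, seed=21)
        s1 = ms.fit(data, graph, cfg)
        s2 = ms.fit(data, graph, cfg)
        np.testing.assert_array_equal(s1.a0, s2.a0)
        np.testing.assert_array_equal(s1.omega, s2.omega)
        np.testing.assert_array_equal(s1.precisions["tau_omega"],
                                      s2.precisions["tau_omega"])

    def test_anomalous_cell_has_largest_omega(self):
        # all structure pinned except omega; one strong anomaly must dominate
        taus = {k: 1e12 for k in ("tau_alpha", "tau_zeta", "tau_phi", "tau_gamma",
                                  "tau_delta", "tau_kappa", "tau_nu")}
        spec = ms.SimulationSpec(rows=3, cols=3, n_age_groups=4, n_years=5,
                                 n_deciles=3, tau_omega=2000.0,
                                 anomalies=[(2, 3, 0.5)], seed=13, **taus)
        data, _ = ms.simulate_dataset(spec)
        graph = ms.make_lattice_graph(3, 3)
        s = ms.fit(data, graph, ms.ModelConfig(n_chains=1, burn_in=300,
                                               n_iter=300, seed=14))
        omega_mean = s.omega.mean(axis=0)
        assert omega_mean[2, 3] > 0
        assert omega_mean[2, 3] == pytest.approx(np.max(omega_mean[2]), abs=1e-12)

    def test_split_chain_diagnostic_on_intercept(self, small_fit):
        report = ms.convergence_report(small_fit)
        rhat_a0 = float(report.set_index("parameter").loc["a0", "rhat"])
        assert rhat_a0 < 1.1

    def test_kept_samples_respect_constraints(self, small_fit):
        tol = 1e-6
        assert np.max(np.abs(small_fit.alpha.sum(axis=1))) < tol
        assert np.max(np.abs(small_fit.gamma.sum(axis=1))) < tol
        assert np.max(np.abs(small_fit.zeta.sum(axis=1))) < tol
        assert np.max(np.abs(small_fit.omega.sum(axis=(1, 2)))) < tol
        assert np.max(np.abs(small_fit.delta.sum(axis=(1, 2)))) < tol
        assert np.max(np.abs(small_fit.kappa.sum(axis=1))) < tol
        assert np.max(np.abs(small_fit.kappa.sum(axis=2))) < tol
        assert np.max(np.abs(small_fit.nu.sum(axis=1))) < tol
        for p, vals in small_fit.precisions.items():
            assert np.all(vals > 0), p

    def test_single_area_rejected(self):
        data = MortalityDataset(
            area_ids=["A0"], age_groups=[(0, 1), (1, None)], years=[2015, 2016],
            sex="female", deaths=np.ones((1, 2, 2), dtype=np.int64),
            population=np.full((1, 2, 2), 100.0), decile={"A0": 1},
        )
        graph = AdjacencyGraph(1, [[]])
        with pytest.raises(ValueError, match="single area"):
            ms.fit(data, graph, ms.ModelConfig(n_chains=1, burn_in=10,
                                               n_iter=100, seed=0))

    def test_disconnected_graph_rejected(self, small_sim):
        _, data, _, _ = small_sim
        neighbors = [[] for _ in range(16)]
        neighbors[0], neighbors[1] = [1], [0]
        for k in range(2, 16, 2):
            neighbors[k], neighbors[k + 1] = [k + 1], [k]
        graph = AdjacencyGraph(16, neighbors)
        with pytest.raises(ValueError, match="connected"):
            ms.fit(data, graph, ms.ModelConfig(n_chains=1, burn_in=10,
                                               n_iter=100, seed=0))

    def test_posterior_contraction_with_population(self):
        # doubling exposure must shrink the posterior sd of the intercept
        sds = []
        for k, scale in enumerate([2e3, 8e3, 32e3]):
            spec = ms.SimulationSpec(rows=3, cols=3, n_age_groups=4, n_years=4,
                                     n_deciles=3, population_scale=scale, seed=31)
            data, _ = ms.simulate_dataset(spec)
            s = ms.fit(data, ms.make_lattice_graph(3, 3),
                       ms.ModelConfig(n_chains=1, burn_in=300, n_iter=400,
                                      seed=32 + k))
            sds.append(s.a0.std())
        assert sds[0] > sds[1] > sds[2]

    def test_save_load_round_trip(self, small_fit, tmp_path):
        small_fit.save(tmp_path / "post")
        back = ms.PosteriorSamples.load(tmp_path / "post")
        np.testing.assert_allclose(back.a0, small_fit.a0)
        np.testing.assert_allclose(back.omega, small_fit.omega)
        assert back.years == small_fit.years
        assert back.area_ids == small_fit.area_ids
        np.testing.assert_array_equal(back.chain, small_fit.chain)


class TestConvergenceReport:
    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(0)
        half = rng.normal(size=200)
        samples = make_posterior(np.concatenate([half, half]), n_chains=2)
        report = ms.convergence_report(samples)
        rhat = float(report.set_index("parameter").loc["a0", "rhat"])
        assert rhat == pytest.approx(1.0, abs=0.01)

    def test_shifted_chain_flagged(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=200)
        samples = make_posterior(np.concatenate([half, half + 5.0]), n_chains=2)
        report = ms.convergence_report(samples).set_index("parameter")
        assert report.loc["a0", "rhat"] > 1.1
        assert bool(report.loc["a0", "flagged"])

    def test_white_noise_ess_near_nominal(self):
        rng = np.random.default_rng(2)
        esses = []
        for _ in range(10):
            samples = make_posterior(rng.normal(size=400), n_chains=2)
            report = ms.convergence_report(samples).set_index("parameter")
            esses.append(float(report.loc["a0", "ess"]))
        assert abs(np.mean(esses) - 400) / 400 < 0.2

    def test_single_chain_rejected(self):
        samples = make_posterior(np.zeros(100), n_chains=1)
        with pytest.raises(ValueError, match="2 chains"):
            ms.convergence_report(samples)
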