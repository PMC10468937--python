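import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import adsim
from adsim.protein import ContractError

from reference import naive_abeta_rhs, naive_gain, naive_loss, naive_tau_rhs


class TestCoagulation:
    def test_zero_state_is_inert(self):
        np.testing.assert_array_equal(adsim.coagulation_gain(np.zeros(5), 7.0), np.zeros(5))
        np.testing.assert_array_equal(adsim.coagulation_loss(np.zeros(5), 7.0), np.zeros(5))

    def test_monomer_pair_forms_dimer(self):
        gain = adsim.coagulation_gain(np.array([1.0, 0, 0, 0, 0]), 2.0)
        np.testing.assert_allclose(gain, [0, 1.0, 0, 0, 0])

    def test_gain_matches_ordered_pair_enumeration(self):
        c = np.array([1.0, 1.0, 1.0, 1.0, 0.0])
        np.testing.assert_allclose(adsim.coagulation_gain(c, 2.0), [0, 1, 2, 3, 10])

    def test_loss_includes_aggregate_compartment(self):
        np.testing.assert_allclose(
            adsim.coagulation_loss(np.array([2.0, 0, 0, 0, 0]), 3.0), [12, 0, 0, 0, 0]
        )
        np.testing.assert_allclose(
            adsim.coagulation_loss(np.ones(5), 1.0), [5, 5, 5, 5, 0]
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ContractError):
            adsim.coagulation_gain(np.array([-1.0, 0, 0, 0, 0]), 1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(0, 2, 5)
        rate = rng.uniform(0, 5)
        np.testing.assert_allclose(adsim.coagulation_gain(c, rate), naive_gain(c, rate),
                                   rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(adsim.coagulation_loss(c, rate), naive_loss(c, rate),
                                   rtol=1e-12, atol=1e-14)


class TestTauSources:
    def test_seed_profile_shape(self):
        lam = 10.0
        assert adsim.tau_seed_source(0.0, lam) == 0.0
        assert adsim.tau_seed_source(lam, lam) == pytest.approx(np.exp(-1))
        assert adsim.tau_seed_source(lam, lam) > adsim.tau_seed_source(5 * lam, lam)
        assert adsim.tau_seed_source(1e6, lam) < 1e-10

    def test_induced_production_threshold(self):
        u = np.array([0.5, 0.002, 0.001, 0.001, 9.0])
        assert adsim.abeta_induced_production(u, C_tau=10.0, U_bar=0.001) == pytest.approx(0.03)
        below = np.array([0.5, 1e-5, 1e-5, 1e-5, 9.0])
        assert adsim.abeta_induced_production(below, C_tau=10.0, U_bar=0.001) == 0.0
        assert adsim.abeta_induced_production(u, C_tau=0.0, U_bar=0.001) == 0.0


def _random_field(rng, n):
    return adsim.ProteinField(rng.uniform(0, 0.5, (n, 5)), rng.uniform(0, 0.5, (n, 5)))


def _random_graph(rng, n):
    w = np.triu(rng.uniform(0.1, 1.0, (n, n)), k=1)
    return adsim.WeightedGraph.from_weights(w + w.T)


class TestAbetaRhs:
    def test_zero_state_zero_production_is_stationary(self):
        g = adsim.WeightedGraph.from_weights([[0, 1.0], [1.0, 0]])
        fld = adsim.ProteinField.zeros(2)
        rhs = adsim.abeta_rhs(fld, g, adsim.scenario_params("C"), np.zeros(2))
        np.testing.assert_array_equal(rhs, np.zeros((2, 5)))

    def test_clearance_rate_scaled_by_epsilon(self):
        # two identical nodes so diffusion vanishes; alpha=0 leaves pure clearance
        g = adsim.WeightedGraph.from_weights([[0, 1.0], [1.0, 0]])
        p = adsim.default_params().with_scenario(0.0, 0.0, 0.0)
        fld = adsim.ProteinField(np.array([[0.3, 0, 0, 0, 0]] * 2), np.zeros((2, 5)))
        rhs = adsim.abeta_rhs(fld, g, p, np.zeros(2))
        np.testing.assert_allclose(rhs[:, 0], -10.0 * 0.3)

    def test_uniform_state_has_no_diffusion_flux(self):
        rng = np.random.default_rng(0)
        g = _random_graph(rng, 6)
        p = adsim.scenario_params("C")
        row = np.array([0.1, 0.02, 0.01, 0.005, 0.2])
        uniform = adsim.ProteinField(np.tile(row, (6, 1)), np.zeros((6, 5)))
        rhs_uniform = adsim.abeta_rhs(uniform, g, p, np.full(6, 0.2))
        # every node must evolve exactly like an isolated one
        np.testing.assert_allclose(rhs_uniform, np.tile(rhs_uniform[0], (6, 1)), atol=1e-14)

    def test_case_e_never_populates_oligomers(self):
        rng = np.random.default_rng(1)
        g = _random_graph(rng, 5)
        p = adsim.scenario_params("E")
        u = np.zeros((5, 5))
        u[:, 0] = rng.uniform(0, 1, 5)
        fld = adsim.ProteinField(u, np.zeros((5, 5)))
        rhs = adsim.abeta_rhs(fld, g, p, rng.uniform(0, 1, 5))
        np.testing.assert_array_equal(rhs[:, 1:], np.zeros((5, 4)))

    def test_pure_diffusion_conserves_pi_weighted_mass(self):
        rng = np.random.default_rng(2)
        g = _random_graph(rng, 8)
        p = adsim.ModelParams(sigma=(0, 0, 0, 0)).with_scenario(0.0, 0.0, 0.0)
        fld = adsim.ProteinField(rng.uniform(0, 1, (8, 5)), np.zeros((8, 5)))
        rhs = adsim.abeta_rhs(fld, g, p, np.zeros(8))
        np.testing.assert_allclose(g.pi @ rhs, np.zeros(5), atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(2, 10), st.integers(0, 10_000))
    def test_matches_naive_transcription(self, n, seed):
        rng = np.random.default_rng(seed)
        g = _random_graph(rng, n)
        p = adsim.scenario_params("C")
        fld = _random_field(rng, n)
        prod = rng.uniform(0, 1, n)
        got = adsim.abeta_rhs(fld, g, p, prod)
        want = naive_abeta_rhs(fld.u, g.weights, p, prod)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)


class TestTauRhs:
    def test_case_a_is_identically_zero(self):
        rng = np.random.default_rng(3)
        g = _random_graph(rng, 4)
        p = adsim.scenario_params("A")
        u = np.zeros((4, 5))
        u[:, 1] = 1.0  # plenty of Abeta oligomers, but C_tau = 0
        fld = adsim.ProteinField(u, np.zeros((4, 5)))
        rhs = adsim.tau_rhs(fld, g, p, t=5.0, seed=np.ones(4))
        np.testing.assert_array_equal(rhs, np.zeros((4, 5)))

    def test_seeding_at_peak_time(self):
        g = adsim.WeightedGraph.from_weights([[0, 1.0], [1.0, 0]])
        p = adsim.scenario_params("B")  # c = 0.05, C_tau = 0
        fld = adsim.ProteinField.zeros(2)
        rhs = adsim.tau_rhs(fld, g, p, t=p.lambda_, seed=np.array([1.0, 0.0]))
        np.testing.assert_allclose(rhs[0, 0], 0.05 * np.exp(-1))
        assert rhs[1, 0] == 0.0

    def test_production_only_where_oligomers_exceed_threshold(self):
        g = adsim.WeightedGraph.from_weights([[0, 1.0], [1.0, 0]])
        p = adsim.scenario_params("D")  # C_tau = 10, c = 0
        u = np.zeros((2, 5))
        u[0, 1] = 0.1
        fld = adsim.ProteinField(u, np.zeros((2, 5)))
        rhs = adsim.tau_rhs(fld, g, p, t=1.0, seed=np.zeros(2))
        assert rhs[0, 0] > 0
        assert rhs[1, 0] == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(2, 10), st.integers(0, 10_000))
    def test_matches_naive_transcription(self, n, seed):
        rng = np.random.default_rng(seed)
        g = _random_graph(rng, n)
        p = adsim.scenario_params("C")
        fld = _random_field(rng, n)
        chi = (rng.uniform(size=n) < 0.5).astype(float)
        t = rng.uniform(0, 20)
        got = adsim.tau_rhs(fld, g, p, t, chi)
        want = naive_tau_rhs(fld.tau, fld.u, g.weights, p, t, chi)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_aggregate_compartments_never_decrease(self, seed):
        """Plaque and tangle derivatives are gain-only, hence nonnegative."""
        rng = np.random.default_rng(seed)
        g = _random_graph(rng, 5)
        p = adsim.scenario_params("C")
        fld = _random_field(rng, 5)
        du = adsim.abeta_rhs(fld, g, p, rng.uniform(0, 1, 5))
        dtau = adsim.tau_rhs(fld, g, p, rng.uniform(0, 20), np.ones(5))
        assert np.all(du[:, 4] >= 0)
        assert np.all(dtau[:, 4] >= 0)
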