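import dataclasses

import numpy as np
import pytest

import adsim
from adsim.engine import StepRejected, build_connectome, step, write_run_log
from adsim.health import AGrid


def _ring(n=6):
    """Vertex-transitive ring with uniform weights, all nodes seeded."""
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
    g = adsim.WeightedGraph.from_weights(w)
    parc = adsim.Parcellation(
        node_ids=tuple(range(1, n + 1)),
        region_labels=("all",),
        region_index=np.zeros(n, dtype=int),
        seed_nodes=np.arange(n),
    )
    return parc, g


class TestInitialize:
    def test_healthy_brain_initial_data(self, triangle_connectome):
        parc, conn, prox = triangle_connectome
        grid = AGrid(21)
        s = adsim.initialize(adsim.scenario_params("C"), parc, conn, prox, grid)
        np.testing.assert_array_equal(s.proteins.u[:, 1:], 0.0)
        np.testing.assert_array_equal(s.proteins.tau, 0.0)
        assert np.all(s.proteins.u[:, 0] == 0.01)
        A0 = adsim.mean_malfunction(s.health.values, grid)
        assert np.all(np.abs(A0 - 0.01) <= grid.delta)

    def test_seeding_requires_seed_nodes(self, triangle_connectome):
        parc, conn, prox = triangle_connectome
        bare = dataclasses.replace(parc, seed_nodes=np.array([], dtype=int))
        with pytest.raises(ValueError, match="V_seed"):
            adsim.initialize(adsim.scenario_params("C"), bare, conn, prox, AGrid(21))

    def test_mismatched_node_sets_rejected(self, triangle_connectome):
        parc, conn, _ = triangle_connectome
        small = adsim.WeightedGraph.from_weights([[0, 1.0], [1.0, 0]])
        with pytest.raises(ValueError, match="node set"):
            adsim.initialize(adsim.scenario_params("C"), parc, conn, small, AGrid(21))


class TestStep:
    def test_zero_dynamics_is_stationary(self, triangle_connectome):
        parc, conn, prox = triangle_connectome
        p = adsim.ModelParams(
            d=(0, 0, 0, 0), d_tilde=(0, 0, 0, 0), sigma=(0, 0, 0, 0),
            C_G=0.0, C_S=0.0, C_T=0.0, C_F=0.0,
        ).with_scenario(0.0, 0.0, 0.0)
        grid = AGrid(21)
        s0 = adsim.initialize(p, parc, conn, prox, grid)
        s1 = step(s0, conn, prox, p, grid, adsim.seed_indicator(parc), dt=0.05)
        np.testing.assert_allclose(s1.proteins.u, s0.proteins.u, atol=1e-14)
        np.testing.assert_allclose(s1.proteins.tau, s0.proteins.tau, atol=1e-14)
        np.testing.assert_allclose(s1.health.values, s0.health.values, atol=1e-14)

    def test_case_e_keeps_oligomers_exactly_zero(self, triangle_connectome):
        parc, conn, prox = triangle_connectome
        p = adsim.scenario_params("E")
        grid = AGrid(21)
        s = adsim.initialize(p, parc, conn, prox, grid)
        for _ in range(5):
            s = step(s, conn, prox, p, grid, adsim.seed_indicator(parc), dt=0.01)
        np.testing.assert_array_equal(s.proteins.u[:, 1:], 0.0)

    def test_cfl_violation_rejects_step(self, triangle_connectome):
        parc, conn, prox = triangle_connectome
        p = adsim.scenario_params("C")
        grid = AGrid(21)
        s = adsim.initialize(p, parc, conn, prox, grid)
        # inflate tau so the toxicity drift forces a CFL breach at huge dt
        s.proteins.tau[:, 0] = 50.0
        with pytest.raises(StepRejected):
            step(s, conn, prox, p, grid, adsim.seed_indicator(parc), dt=5.0)

    def test_splitting_error_is_second_order_per_step(self, triangle_connectome):
        """One full step vs two half steps: the gap must shrink ~4x with dt/2."""
        parc, conn, prox = triangle_connectome
        p = adsim.scenario_params("C")
        grid = AGrid(21)
        chi = adsim.seed_indicator(parc)
        s0 = adsim.initialize(p, parc, conn, prox, grid)
        # move off the trivial initial state first
        for _ in range(10):
            s0 = step(s0, conn, prox, p, grid, chi, dt=0.01)

        def gap(dt):
            full = step(s0, conn, prox, p, grid, chi, dt)
            half = step(
                step(s0, conn, prox, p, grid, chi, dt / 2), conn, prox, p, grid, chi, dt / 2
            )
            return max(
                np.abs(full.proteins.u - half.proteins.u).max(),
                np.abs(full.health.values - half.health.values).max(),
            )

        g1, g2 = gap(0.04), gap(0.02)
        assert g2 < g1 / 2.5


class TestSimulate:
    def test_symmetry_on_vertex_transitive_graph(self):
        parc, ring = _ring(6)
        traj = adsim.simulate(
            adsim.scenario_params("C"), parc, ring, ring,
            t_end=2.0, a_cells=21, sample_dt=0.5,
        )
        u = traj.final_state.proteins.u
        tau = traj.final_state.proteins.tau
        f = traj.final_state.health.values
        assert np.abs(u - u[0]).max() < 1e-12
        assert np.abs(tau - tau[0]).max() < 1e-12
        assert np.abs(f - f[0]).max() < 1e-10

    def test_trajectory_invariants_small_run(self, small_run):
        tr = small_run
        assert np.all(np.diff(tr.times) > 0)
        assert np.abs(tr.f_mass - 1.0).max() < 1e-10
        assert np.all(np.diff(tr.A_node, axis=0) >= -1e-12)
        assert np.all(np.diff(tr.u_global[:, 4]) >= 0)
        assert np.all(np.diff(tr.tau_global[:, 4]) >= 0)
        assert tr.u_global.min() >= 0 and tr.tau_global.min() >= 0

    def test_case_a_has_no_tau_anywhere(self):
        cfg = adsim.RunConfig(
            case="A", params=adsim.scenario_params("A"),
            synthetic=adsim.SyntheticSpec(16, 4, 3), t_end=2.0, a_cells=21,
        )
        tr = adsim.run(cfg)
        assert np.abs(tr.tau_global).max() == 0.0
        assert np.abs(tr.final_state.proteins.tau).max() == 0.0

    def test_deterministic_given_config(self):
        cfg = adsim.RunConfig(
            case="C", params=adsim.scenario_params("C"),
            synthetic=adsim.SyntheticSpec(12, 3, 5), t_end=1.0, a_cells=21,
        )
        a, b = adsim.run(cfg), adsim.run(cfg)
        np.testing.assert_array_equal(a.u_global, b.u_global)
        np.testing.assert_array_equal(a.A_node, b.A_node)
        np.testing.assert_array_equal(a.final_state.health.values, b.final_state.health.values)

    def test_run_log_written(self, small_run, tmp_path):
        path = tmp_path / "log.json"
        write_run_log(small_run, path)
        import json

        log = json.loads(path.read_text())
        assert log["case"] == "C"
        assert log["n_steps"] > 0
        assert "connectivity_hash" in log

    def test_build_connectome_requires_coords_for_files(self, tmp_path):
        edges = tmp_path / "e.csv"
        edges.write_text("node_i,node_j,weight\n1,2,1.0\n2,3,1.0\n1,3,1.0\n")
        parcels = tmp_path / "p.csv"
        parcels.write_text("node_id,region,seed\n1,EC,1\n2,b,0\n3,c,0\n")
        cfg = adsim.RunConfig(
            case="C", params=adsim.scenario_params("C"), synthetic=None,
            edges_path=str(edges), parcels_path=str(parcels), t_end=1.0, a_cells=21,
        )
        with pytest.raises(ValueError, match="coordinates"):
            build_connectome(cfg)
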