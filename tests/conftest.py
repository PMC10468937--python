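import numpy as np
import pytest

import adsim


@pytest.fixture(scope="session")
def triangle_connectome():
    """Tiny hand-built connectome: 3 nodes, 3 singleton regions, one seed node."""
    w_conn = np.array([[0.0, 1.0, 0.5], [1.0, 0.0, 0.8], [0.5, 0.8, 0.0]])
    w_prox = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 0.4], [1.0, 0.4, 0.0]])
    parc = adsim.Parcellation(
        node_ids=(1, 2, 3),
        region_labels=("EC", "r2", "r3"),
        region_index=np.array([0, 1, 2]),
        seed_nodes=np.array([0]),
    )
    return parc, adsim.WeightedGraph.from_weights(w_conn), adsim.WeightedGraph.from_weights(w_prox)


def _campaign_config(case: str, **overrides) -> adsim.RunConfig:
    """The study configuration: 64-node / 8-region synthetic connectome, T=50."""
    kwargs = dict(
        case=case,
        params=adsim.scenario_params(case),
        synthetic=adsim.SyntheticSpec(n_nodes=64, n_regions=8, rng_seed=1),
        t_end=50.0,
        a_cells=101,
        sample_dt=0.25,
    )
    kwargs.update(overrides)
    return adsim.RunConfig(**kwargs)


@pytest.fixture(scope="session")
def campaign():
    """Lazily-cached scenario runs shared by the acceptance tests."""
    cache: dict = {}

    def get(case: str, **overrides) -> adsim.Trajectory:
        key = (case, tuple(sorted(overrides.items())))
        if key not in cache:
            cache[key] = adsim.run(_campaign_config(case, **overrides))
        return cache[key]

    return get


@pytest.fixture()
def small_run():
    """A quick 16-node case-C run for observable-level tests."""
    cfg = adsim.RunConfig(
        case="C",
        params=adsim.scenario_params("C"),
        synthetic=adsim.SyntheticSpec(n_nodes=16, n_regions=4, rng_seed=3),
        t_end=3.0,
        a_cells=21,
        sample_dt=0.5,
    )
    return adsim.run(cfg)
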