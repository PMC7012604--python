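import numpy as np
import pytest

from olivenet import net_sim, network_gen


FIG_PROFILE = network_gen.ConnectivityProfile(
    sigma_max_within=77.0, sigma_decay_within=45.0,
    sigma_max_between=15.0, sigma_decay_between=20.0, cluster_size=40)


@pytest.fixture(scope="session")
def clustered_profile():
    """The clustered-network connectivity profile used throughout the study."""
    return FIG_PROFILE


@pytest.fixture(scope="session")
def validation_network():
    """The 180-neuron validation network with its coupling map."""
    geom = network_gen.place_neurons(180, (125.0, 250.0, 100.0), seed=7)
    geom = network_gen.cluster_neurons(geom, 40, seed=7)
    conn = network_gen.build_connectome(geom, FIG_PROFILE, seed=7)
    coupling = net_sim.build_coupling_map(conn, seed=7)
    return conn, coupling


@pytest.fixture(scope="session")
def large_clustered_network():
    """One realization of the full-size (1134-neuron) clustered network."""
    geom = network_gen.place_neurons(1134, (250.0, 500.0, 200.0), seed=0)
    geom = network_gen.cluster_neurons(geom, 40, seed=0)
    return network_gen.build_connectome(geom, FIG_PROFILE, seed=0)


def random_connectome(n: int, p: float, seed: int) -> network_gen.Connectome:
    """Erdos-Renyi adjacency wrapped as a Connectome, for graph-level tests."""
    rng = np.random.default_rng(seed)
    adjacency = np.triu(rng.random((n, n)) < p, k=1)
    adjacency = adjacency | adjacency.T
    geom = network_gen.NetworkGeometry(
        positions=rng.uniform(0, 100, size=(n, 3)), volume=(100.0,) * 3,
        seed=seed, cluster_label=np.zeros(n, dtype=int))
    return network_gen.Connectome(adjacency=adjacency, geometry=geom,
                                  profile=FIG_PROFILE, seed=seed)
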