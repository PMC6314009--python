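import numpy as np
import pytest

import symptomnet as sn


def make_study_run(seed: int, **overrides):
    """Generate one study-like cohort and estimate its network (defaults)."""
    config = sn.GeneratorConfig(seed=seed, **overrides)
    frame, truth = sn.generate_cohort(config)
    data, log = sn.prepare_matrix(frame)
    graph, params = sn.estimate_network(data)
    return {
        "config": config,
        "truth": truth,
        "data": data,
        "log": log,
        "graph": graph,
        "params": params,
    }


@pytest.fixture(scope="session")
def study_runs():
    """Ten seeded study-like cohorts with estimated networks (defaults)."""
    return [make_study_run(seed) for seed in range(10)]


@pytest.fixture(scope="session")
def nobridge_runs():
    """Ten cohorts with zero bridge couplings, plus walktrap partitions."""
    runs = []
    for seed in range(10):
        run = make_study_run(seed, n_bridge_edges=0)
        run["partition"] = sn.walktrap(run["graph"])
        runs.append(run)
    return runs


@pytest.fixture(scope="session")
def chain4_params():
    """4-node chain Ising model with unit adjacent couplings."""
    omega = np.zeros((4, 4))
    for i in range(3):
        omega[i, i + 1] = omega[i + 1, i] = 1.0
    tau = np.array([-1.0, -0.5, -0.8, -1.2])
    return sn.IsingParameters(tau, omega)


@pytest.fixture
def small_data():
    """Small prepared dataset from a 6-node two-cluster model."""
    config = sn.GeneratorConfig(
        n=400,
        cluster_sizes=(3, 3),
        seed=7,
        n_bridge_edges=1,
        target_endorsement_rates=np.linspace(0.2, 0.5, 6),
    )
    frame, truth = sn.generate_cohort(config)
    data, _ = sn.prepare_matrix(frame)
    return data, truth
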