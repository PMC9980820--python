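import numpy as np
import pandas as pd
import pytest

from boldsim import SimulationConfig, run_simulation
from boldsim.experiments import published_sweep, run_sweep
from boldsim.fixtures import generate_fixtures


@pytest.fixture(scope="session")
def micro_tables():
    """Deterministic micro-sweep bundle (focal + full-group tables)."""
    return generate_fixtures(seed=0)


@pytest.fixture(scope="session")
def baseline_cell_logs():
    """200 replicate event logs per rule at the study baselines.

    Uses the one-based boldness indexing, the variant consistent with the
    published group-level outcomes (see docs/methods.md).
    """
    logs = {}
    for rule in ("central", "nearest_neighbour", "majority", "non_social"):
        logs[rule] = [
            run_simulation(SimulationConfig(rule=rule, seed=20_000 + i,
                                            omega_indexing="one_based"))
            for i in range(200)
        ]
    return logs


@pytest.fixture(scope="session")
def omega_sweep_full_group():
    """Full published omega_difference sweep, 200 reps/cell, all four rules,
    full-group protocol, one-based indexing (the variance-partitioning and ordering-difference
    reproduction dataset)."""
    design = published_sweep("omega_difference", replicates=200,
                             master_seed=11, omega_indexing="one_based")
    return run_sweep(design, protocol="full_group")
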