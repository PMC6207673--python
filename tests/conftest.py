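import numpy as np
import pandas as pd
import pytest

from cardiomod.simulate import ModuleSpec, SimConfig, simulate_cells


def small_config(seed=0, **overrides):
    """400 genes x 120 cells, two planted modules: fast shared fixture."""
    cfg = SimConfig(
        n_genes=400,
        n_cells_per_stage={"sham": 40, "w1": 40, "w8": 40},
        modules=[ModuleSpec(60), ModuleSpec(40)],
        stage_activity=np.array([[0.0, 2.0, -2.0], [2.0, -2.0, 0.0]]),
        stage_specific_module=None,
        noise_sd=1.0,
        dropout_rate=0.1,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_cells(small_config())


@pytest.fixture()
def toy_matrix():
    """Tiny hand-checkable matrix: 4 genes x 3 cells."""
    return pd.DataFrame(
        [
            [0.05, 0.2, 11.0],
            [0.0, 0.0, 0.0],
            [10.0, 0.0, 0.0],
            [5.0, 9.0, 12.0],
        ],
        index=["g1", "g2", "g3", "g4"],
        columns=["c1", "c2", "c3"],
    )
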