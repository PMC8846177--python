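import numpy as np
import pandas as pd
import pytest

import graftgrn as gg


def make_matrix(values: np.ndarray, tps=(1, 3, 5), reps=4, combo="X",
                genes=None) -> gg.ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with a standard design."""
    samples = [f"{combo}_{t}d_r{r}" for t in tps for r in range(1, reps + 1)]
    assert values.shape[1] == len(samples)
    meta = pd.DataFrame(
        {
            "combination": combo,
            "timepoint": [t for t in tps for _ in range(reps)],
            "replicate": [r for _ in tps for r in range(1, reps + 1)],
        },
        index=samples,
    )
    if genes is None:
        genes = [f"g{i:04d}" for i in range(values.shape[0])]
    return gg.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)


@pytest.fixture(scope="session")
def small_config() -> gg.SyntheticConfig:
    return gg.SyntheticConfig(n_tfs=8, n_targets=30, n_flat_genes=10,
                              parents_per_target=2, seed=11)


@pytest.fixture(scope="session")
def small_network(small_config):
    return gg.generate_planted_network(small_config)


@pytest.fixture(scope="session")
def small_study(small_config):
    return gg.generate_study(small_config)


@pytest.fixture(scope="session")
def small_go(small_network):
    return gg.generate_go_resources(small_network, n_terms=40, dag_depth=3,
                                    graft_related_fraction=0.5, seed=11)
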