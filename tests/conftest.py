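import numpy as np
import pandas as pd
import pytest

from repbench.de_tests import DEResult, TestConfig
from repbench.experiment_io import CountMatrix, ExperimentDesign
from repbench.synthetic_data import GeneratorConfig, simulate_experiment


@pytest.fixture
def tiny_cm() -> CountMatrix:
    return CountMatrix.from_arrays(
        ["gA", "gB", "gC"], ["s1", "s2", "s3", "s4"],
        [[5, 6, 50, 60], [10, 12, 11, 13], [0, 1, 100, 90]],
    )


@pytest.fixture
def tiny_design() -> ExperimentDesign:
    return ExperimentDesign({"s1": "ctrl", "s2": "ctrl", "s3": "mut", "s4": "mut"})


@pytest.fixture(scope="session")
def small_experiment():
    """Scaled-down synthetic experiment shared across benchmark tests."""
    cfg = GeneratorConfig(seed=20240, n_genes=400, n_rep=10)
    return simulate_experiment(cfg)


def make_result(gene_ids, sde_flags, caller="stub", log2fc=None) -> DEResult:
    """Hand-built DEResult for set-algebra / concordance oracles."""
    sde = np.asarray(sde_flags, dtype=bool)
    p = np.where(sde, 0.001, 0.9)
    table = pd.DataFrame(
        {"log2fc": np.zeros(len(gene_ids)) if log2fc is None else log2fc,
         "p": p, "p_adj": p, "sde": sde},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return DEResult(table=table, caller=caller, config=TestConfig())
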