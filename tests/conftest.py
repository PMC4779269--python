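import numpy as np
import pandas as pd
import pytest

import lowphos as lp


@pytest.fixture
def config():
    return lp.PipelineConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """One default-scenario dataset shared by read-only tests."""
    spec = lp.default_scenario(rng_seed=11, n_genes=600)
    return lp.simulate_dataset(spec)


@pytest.fixture(scope="session")
def quiet_dataset():
    """Near-noise-free dataset: the deterministic limit of the generator."""
    spec = lp.default_scenario(rng_seed=13, n_genes=600)
    spec.noise_sd = 1e-6
    return lp.simulate_dataset(spec)


def make_contrast_table(rows):
    """Build a minimal contrast-result table from (gene_id, log2_ratio,
    q_value, n_reps) tuples, applying the three-part DEG criterion."""
    df = pd.DataFrame(
        rows, columns=["gene_id", "log2_ratio", "q_value", "n_complete_replicates"]
    ).set_index("gene_id")
    df["fold_change"] = np.exp2(df["log2_ratio"])
    df["is_deg"] = (
        (df["log2_ratio"].abs() >= 1.0)
        & (df["q_value"] < 0.05)
        & (df["n_complete_replicates"] >= 3)
    )
    df["direction"] = np.where(
        ~df["is_deg"], "none", np.where(df["log2_ratio"] > 0, "up", "down")
    )
    return df
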