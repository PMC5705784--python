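import numpy as np
import pandas as pd
import pytest

from neurocascade import CascadeTruth, default_truths, generate_dataset, summarize


@pytest.fixture(scope="session")
def default_dataset():
    """The package's stated four-age synthetic world, one fixed draw."""
    obs, truths = generate_dataset(default_truths(), n_per_group=5, seed=42)
    return obs, truths


@pytest.fixture(scope="session")
def default_summaries(default_dataset):
    obs, _ = default_dataset
    return summarize(obs)


def degenerate_summaries(means: dict, gfap_pct: float, neun_pct: float,
                         age: float = 1.0) -> pd.DataFrame:
    """Zero-SD summary table for one age (deterministic simulation input)."""
    rows = [(age, tp, "total", m, 0.0, 5) for tp, m in means.items()]
    rows += [
        (age, "30d", "GFAP_pct", gfap_pct, 0.0, 5),
        (age, "30d", "NeuN_pct", neun_pct, 0.0, 5),
    ]
    return pd.DataFrame(
        rows, columns=["age_months", "timepoint", "marker", "mean", "sd", "n"]
    )
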