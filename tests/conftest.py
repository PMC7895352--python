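import numpy as np
import pandas as pd
import pytest

import retrostress as rs


@pytest.fixture(scope="session")
def default_sim():
    """Default-generator dataset (seed 1): counts, design, truth."""
    return rs.generate_counts(rs.SimConfig(), seed=1)


@pytest.fixture(scope="session")
def default_norm(default_sim):
    cm, design, truth = default_sim
    return rs.normalize(cm)


@pytest.fixture(scope="session")
def de_bench():
    """Constant-dispersion DE benchmark dataset (seed 1) plus its DE result."""
    cfg = rs.de_benchmark_config()
    cm, design, truth = rs.generate_counts(cfg, seed=1)
    norm = rs.normalize(cm)
    de = rs.call_de(norm.values, design, [("THP1_5", "THP1_0"), ("MDM_5", "MDM_0")])
    return cm, design, truth, norm, de


@pytest.fixture()
def small_counts():
    df = pd.DataFrame(
        {"s1": [10, 0, 5], "s2": [90, 3, 7]},
        index=["ACTB", "AluY:Alu:SINE", "GENE1"],
    )
    return rs.CountMatrix(df)


@pytest.fixture()
def design_4groups():
    rows = []
    for ct, n in (("THP1", 3), ("MDM", 4)):
        for dose in (0.0, 5.0):
            for r in range(1, n + 1):
                rows.append(
                    {
                        "sample_id": f"{ct}_{dose:g}_{r}",
                        "cell_type": ct,
                        "dose_Gy": dose,
                        "replicate_id": f"r{r}",
                    }
                )
    return rs.build_design(pd.DataFrame(rows))


def random_counts(rng, n_features=50, n_samples=7, high=1000):
    df = pd.DataFrame(
        rng.integers(0, high, size=(n_features, n_samples)),
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    df.iloc[0] += 1  # guard against an all-zero column
    return rs.CountMatrix(df)
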