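import numpy as np
import pandas as pd
import pytest

import panelforge as pf


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with clear planted structure, shared across tests."""
    cfg = pf.SimConfig(
        n_per_subtype=15,
        n_genes=400,
        n_cpgs=300,
        n_informative_genes=20,
        n_informative_cpgs=15,
        seed=11,
    )
    return pf.simulate_multiomic(cfg)


@pytest.fixture()
def tiny_matrix():
    df = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2"],
    )
    return pf.OmicsMatrix(df, "expression")


@pytest.fixture()
def sheet_903060():
    """Sample sheet with subtype sizes 40 / 60 / 30."""
    sizes = {"Classical": 40, "Mesenchymal": 60, "Proneural": 30}
    rows = []
    i = 0
    for st, k in sizes.items():
        for _ in range(k):
            rows.append({"sample_id": f"s{i:03d}", "subtype": st, "batch": "b0", "role": "train"})
            i += 1
    return pf.SampleSheet(pd.DataFrame(rows))


@pytest.fixture()
def demo_panel():
    return pf.Panel(
        subtype="Classical",
        features=[
            ("g1", "expression", "+"),
            ("g2", "expression", "+"),
            ("g3", "expression", "-"),
            ("g4", "expression", "-"),
            ("g5", "expression", "+"),
        ],
        centroid_target=np.array([1.0, 0.8, -0.9, -1.1, 0.5]),
        centroid_control=np.array([-0.5, -0.4, 0.45, 0.55, -0.25]),
        centroid_se=np.array([0.01, 0.01, 0.02, 0.01, 0.03]),
        scale=np.array([1.0, 1.1, 0.9, 1.0, 1.2]),
        priors=(1 / 3, 2 / 3),
        mean_error_rate=0.05,
        sd_error_rate=0.01,
        mean_auc=0.98,
        sd_auc=0.01,
        n_iterations=25,
    )
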