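import numpy as np
import pytest

import leadlasso as ll


@pytest.fixture(scope="session")
def small_codebook() -> ll.Codebook:
    """Compact instrument: 1 continuous + 1 binary + one 4-category item."""
    return ll.Codebook(
        (
            ll.CodebookEntry("height_cm", "continuous"),
            ll.CodebookEntry("sex", "binary", ("boy", "girl")),
            ll.CodebookEntry("wash_hands", "ordinal", ("no", "occasional", "often", "always")),
        )
    )


@pytest.fixture(scope="session")
def default_survey() -> ll.SurveyDataset:
    """One default-condition synthetic survey (both areas)."""
    return ll.generate_survey(ll.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def exposed_survey() -> ll.SurveyDataset:
    """Exposed-area-only survey at the risk-factor-analysis sample size."""
    return ll.generate_survey(
        ll.SimulationConfig(n_children=334, area_split=1.0, seed=42)
    )


@pytest.fixture(scope="session")
def exposed_encoded(exposed_survey) -> ll.EncodedDataset:
    return ll.encode_dummies(exposed_survey, drop_constant_columns=True)


def random_grouped_problem(rng, n, group_sizes, signal=None):
    """Small standardized grouped-logistic instance for solver tests."""
    p = sum(group_sizes)
    X = rng.normal(size=(n, p))
    eta = X @ (signal if signal is not None else np.zeros(p))
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    if y.min() == y.max():  # ensure two classes
        y[0] = 1 - y[0]
    names = [f"g{i}" for i in range(len(group_sizes))]
    cols = [f"g{i}_c{j}" for i, k in enumerate(group_sizes) for j in range(k)]
    enc = ll.EncodedDataset(
        y=y,
        X=X,
        group_index=np.repeat(np.arange(len(group_sizes)), group_sizes),
        group_names=names,
        df=np.asarray(group_sizes),
        column_names=cols,
        row_ids=np.arange(n),
    )
    return ll.standardize_groups(enc)
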