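import numpy as np
import pandas as pd
import pytest

from affectdim import CATEGORIES, StimulusTable, SyntheticConfig, generate


def make_stimulus_frame(n_per_category=2, rng=None):
    """Small hand-constructed valid stimulus frame with one-hot probabilities."""
    rows = []
    i = 0
    for c_idx, cat in enumerate(CATEGORIES):
        for _ in range(n_per_category):
            row = {
                "video_id": f"v{i:03d}",
                "category": cat,
                "valence": 5.0,
                "arousal": 5.0,
            }
            for j, c in enumerate(CATEGORIES):
                row[f"endorse_{c}"] = 1.0 if j == c_idx else 0.0
                row[f"prob_{c}"] = 1.0 if j == c_idx else 0.0
            rows.append(row)
            i += 1
    df = pd.DataFrame(rows)
    if rng is not None:
        # perturb towards generic values while keeping invariants
        n = len(df)
        df["valence"] = rng.uniform(1, 9, n)
        df["arousal"] = rng.uniform(1, 9, n)
        for c in CATEGORIES:
            df[f"endorse_{c}"] = rng.uniform(0, 1, n)
        p = rng.dirichlet(np.ones(5), n)
        for j, c in enumerate(CATEGORIES):
            df[f"prob_{c}"] = p[:, j]
    return df


@pytest.fixture
def onehot_table():
    return StimulusTable.from_frame(make_stimulus_frame())


@pytest.fixture
def random_table():
    rng = np.random.default_rng(7)
    return StimulusTable.from_frame(make_stimulus_frame(6, rng=rng))


@pytest.fixture(scope="session")
def discrete_table():
    table, _ = generate(SyntheticConfig(regime="discrete", seed=11))
    return table


@pytest.fixture(scope="session")
def core_affect_table():
    table, _ = generate(SyntheticConfig(regime="core_affect", seed=11))
    return table
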