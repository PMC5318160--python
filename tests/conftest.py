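import numpy as np
import pandas as pd
import pytest

from circaphase import ExpressionDataset, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort: 8 participants, 200 features, default noise/trait."""
    cfg = SyntheticConfig(n_participants=8, n_features=200, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-scale cohort (20 participants, 1000 features)."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture()
def toy_dataset():
    """4 samples x 10 features with flags, two participants, known phases."""
    rng = np.random.default_rng(5)
    features = [f"F{i}" for i in range(10)]
    samples = [f"s{i}" for i in range(4)]
    values = pd.DataFrame(
        rng.normal(8, 1, size=(10, 4)), index=features, columns=samples
    )
    flags = pd.DataFrame(0, index=features, columns=samples)
    meta = pd.DataFrame(
        {
            "participant_id": ["p1", "p1", "p2", "p2"],
            "condition": ["in_phase", "in_phase", "out_of_phase", "out_of_phase"],
            "batch": ["B0"] * 4,
            "clock_time_h": [22.0, 1.0, 22.0, 1.0],
            "phase_deg": [0.0, 45.0, 90.0, 135.0],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionDataset(values=values, samples=meta, flags=flags)


def noiseless_cosine_dataset(n_participants=4, n_features=12, samples_per=8, seed=3):
    """Noiseless cohort whose features are exact cosines of the sample phase;
    ground truth for closed-form recovery tests."""
    rng = np.random.default_rng(seed)
    acro = rng.uniform(0, 360, size=n_features)
    rows, cols, meta = [], [], []
    for p in range(n_participants):
        # jittered spacing so pooled observed phases keep a nonzero resultant
        offset = rng.uniform(0, 45)
        jitter = rng.uniform(-10, 10, size=samples_per)
        for j in range(samples_per):
            theta = (offset + j * 360.0 / samples_per + jitter[j]) % 360.0
            sid = f"p{p}_s{j}"
            cols.append(sid)
            rows.append(np.cos(np.deg2rad(theta - acro)))
            meta.append((sid, f"p{p}", "in_phase", "B0", theta / 15.0, theta))
    values = pd.DataFrame(
        np.column_stack(rows),
        index=[f"F{i}" for i in range(n_features)],
        columns=cols,
    )
    samples = pd.DataFrame(
        meta,
        columns=[
            "sample_id", "participant_id", "condition", "batch",
            "clock_time_h", "phase_deg",
        ],
    ).set_index("sample_id")
    return ExpressionDataset(values=values, samples=samples)
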