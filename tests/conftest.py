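import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from erscreen import LabeledDataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(values, labels=None, ids=None, columns=None) -> LabeledDataset:
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    ids = ids or [f"c{i+1}" for i in range(n)]
    columns = columns or [f"D{j+1}" for j in range(d)]
    matrix = pd.DataFrame(values, index=pd.Index(ids, name="compound_id"), columns=columns)
    lab = None if labels is None else pd.Series(labels, index=matrix.index)
    return LabeledDataset(matrix, lab)


@pytest.fixture
def separable_1d() -> LabeledDataset:
    return make_dataset([[1.0], [2.0], [8.0], [9.0]], labels=[0, 0, 1, 1], columns=["x"])


@pytest.fixture
def xor_dataset() -> LabeledDataset:
    """Two descriptors, label = XOR of their signs; n=40, jittered, seeded."""
    rng = np.random.default_rng(7)
    signs = np.array([(sx, sy) for sx in (-1, 1) for sy in (-1, 1)])
    pts = []
    labels = []
    for sx, sy in signs:
        x = sx * rng.uniform(0.5, 2.0, size=10)
        y = sy * rng.uniform(0.5, 2.0, size=10)
        pts.append(np.column_stack([x, y]))
        labels.extend([int((sx > 0) != (sy > 0))] * 10)
    return make_dataset(np.vstack(pts), labels=labels, columns=["x", "y"])


@pytest.fixture
def descriptor_csv(tmp_path):
    path = tmp_path / "table.csv"
    path.write_text(
        "compound_id,D1,D2,D3,D4,label\n"
        "cpd1,0.5,1.0,3.5,2,1\n"
        "cpd2,0.1,2.0,3.5,4,0\n"
        "cpd3,0.9,3.0,1.5,6,1\n"
    )
    return path
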