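import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from metabopanel.tables import METADATA_COLUMNS, FeatureTable  # noqa: E402


def make_feature_table(values, injection_order=None, roles=None, batch="B1"):
    """Small hand-built FeatureTable for unit tests.

    ``values`` is an (n_samples × n_features) array-like; NaN marks
    missing entries.
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    ids = [f"S{i + 1}" for i in range(n)]
    if injection_order is None:
        injection_order = list(range(1, n + 1))
    if roles is None:
        roles = ["subject"] * n
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "role": roles,
            "group": ["NA"] * n,
            "cohort": "unit",
            "subtype": "NA",
            "response": "NA",
            "injection_order": injection_order,
            "batch": batch,
        },
        index=ids,
    )[METADATA_COLUMNS]
    meta.index.name = None
    intens = pd.DataFrame(values, index=ids, columns=[f"F{j + 1}" for j in range(m)])
    return FeatureTable(intens, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240805)
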