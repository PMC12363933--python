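import numpy as np
import pandas as pd
import pytest

from morbiditrail.conditions import DISEASE_COLUMNS


def make_panel(rows):
    """Build a panel DataFrame from compact row dicts, filling defaults."""
    defaults = {
        "age": 60.0, "sex": "female", "race": "white", "bmi": 32.0,
        **dict.fromkeys(DISEASE_COLUMNS, 0),
    }
    full = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        d.setdefault("time_years", 2.0 * d["wave"])
        full.append(d)
    return pd.DataFrame(full)


@pytest.fixture
def toy_transactions():
    """Six transactions over {CVD, MTD, SMD} used for hand-computed oracles."""
    return [
        {"CVD"},
        {"CVD", "MTD"},
        {"MTD"},
        {"CVD", "MTD", "SMD"},
        {"SMD"},
        {"CVD", "SMD"},
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
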