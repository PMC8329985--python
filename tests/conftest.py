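import numpy as np
import pandas as pd
import pytest

from powercontours import TrialTable


def make_table(values_by_participant, condition="A"):
    """Build a TrialTable from {participant: [trial values]}."""
    rows = []
    for p, vals in values_by_participant.items():
        for t, v in enumerate(vals):
            rows.append({"participant": p, "condition": condition,
                         "trial": t, "value": v})
    return TrialTable(pd.DataFrame(rows))


def merge_tables(*tables):
    return TrialTable(pd.concat([t.data for t in tables],
                                ignore_index=True))


@pytest.fixture
def tiny_table():
    """Four participants, one condition, four trials each."""
    rng = np.random.default_rng(0)
    return make_table({f"p{i}": rng.normal(1.0, 0.5, 4) for i in range(4)})


@pytest.fixture
def paired_table():
    """Five participants, two conditions, six trials each."""
    rng = np.random.default_rng(1)
    a = make_table({f"p{i}": rng.normal(2.0, 1.0, 6) for i in range(5)},
                   condition="A")
    b = make_table({f"p{i}": rng.normal(1.0, 1.0, 6) for i in range(5)},
                   condition="B")
    return merge_tables(a, b)
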