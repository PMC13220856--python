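import numpy as np
import pandas as pd
import pytest

from promoterlab.families import MutantFamily
from promoterlab.readproc import BinCountTable


@pytest.fixture
def simple_counts() -> BinCountTable:
    """Two sequences, one channel, two replicates, hand-checkable."""
    rows = []
    data = {
        ("s1", 1): [10, 10, 0, 0],  # fluor 1.5
        ("s1", 2): [0, 20, 20, 0],  # fluor 2.5
        ("s2", 1): [0, 0, 0, 40],  # fluor 4.0
        ("s2", 2): [0, 0, 0, 0],  # undefined
    }
    for (sid, rep), reads in data.items():
        for b, r in zip((1, 2, 3, 4), reads):
            rows.append(
                {"sequence_id": sid, "channel": "GFP", "bin": b,
                 "replicate": rep, "reads": r}
            )
    return BinCountTable(pd.DataFrame(rows))


@pytest.fixture
def toy_family() -> MutantFamily:
    """Six daughters of a 12-bp parent; position 4 (1-based) controls
    fluorescence perfectly, every other position is constant."""
    parent = "AACCGGTTAACC"
    daughters, fluor = [], []
    for base, f in [("C", 1.0), ("G", 4.0), ("C", 1.0), ("G", 4.0),
                    ("C", 1.0), ("G", 4.0)]:
        daughters.append(parent[:3] + base + parent[4:])
        fluor.append(f)
    return MutantFamily(
        "toy", parent, daughters, {"GFP": np.asarray(fluor)}
    )
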