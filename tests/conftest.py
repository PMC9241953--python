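import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pullcall import CountTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def write_tsv(path, text: str) -> str:
    path.write_text(text.replace(" | ", "\t"), encoding="utf-8")
    return str(path)


@pytest.fixture
def toy_table() -> CountTable:
    """Four preys + bait across three assays, with lengths attached."""
    counts = pd.DataFrame(
        {
            "a1": [50, 10, 0, 3, 2],
            "a2": [40, 8, 6, 0, 1],
            "a3": [60, 12, 9, 4, 0],
        },
        index=pd.Index(["BAIT", "P1", "P2", "P3", "P4"], name="protein_id"),
    )
    counts.columns.name = "assay_id"
    table = CountTable(counts=counts, bait_id="BAIT")
    return table.attach_lengths({"BAIT": 500, "P1": 200, "P2": 300, "P3": 100, "P4": 400})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
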