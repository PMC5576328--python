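import numpy as np
import pandas as pd
import pytest

from microconcord.io_formats import (
    CountTable,
    PairRecord,
    SamplePairing,
    TaxaTable,
    read_newick_string,
)


@pytest.fixture
def small_table():
    return CountTable(
        pd.DataFrame(
            {"S1": [3, 0, 7], "S2": [1, 4, 5]},
            index=["OTU_1", "OTU_2", "OTU_3"],
        )
    )


@pytest.fixture
def three_leaf_tree():
    return read_newick_string("((A:1,B:2):0.5,C:3):0;")


@pytest.fixture
def pairing_two():
    return SamplePairing(
        (
            PairRecord("p1", "p1.I", "p1.S", "stable"),
            PairRecord("p2", "p2.I", "p2.S", "exacerbation"),
        )
    )


def make_taxa_table(columns: dict, labels=None) -> TaxaTable:
    n = len(next(iter(columns.values())))
    if labels is None:
        labels = [f"taxon_{i}" for i in range(n)]
    return TaxaTable(pd.DataFrame(columns, index=labels))
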