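import numpy as np
import pandas as pd
import pytest

from qpcrkit import CtTable, datasets, standard_curve


@pytest.fixture(scope="session")
def ct1():
    """Brain/kidney c-myc+GAPDH table, 6 replicates per tissue (corrected)."""
    return datasets.ct1()


@pytest.fixture(scope="session")
def ct3():
    """Seven-dilution triplicate series for c-myc and GAPDH."""
    return datasets.ct3()


@pytest.fixture(scope="session")
def curves(ct3):
    """Per-gene standard curves fit from the dilution series."""
    return {c.gene: (c.slope, c.intercept) for c in standard_curve(ct3)}


def make_group_table(delta_cts_by_group, ref_ct=20.0, target="target", ref="ref"):
    """Two-gene table whose per-row delta CTs equal the given values."""
    rows, labels = [], []
    for label, dcts in delta_cts_by_group.items():
        for d in dcts:
            rows.append({target: ref_ct + d, ref: ref_ct})
            labels.append(label)
    return CtTable(pd.DataFrame(rows), group=np.array(labels, dtype=object))
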