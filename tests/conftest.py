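import numpy as np
import pandas as pd
import pytest

from gaitscreen import GaitTable, LookupTable, StudyDataset, join_metadata


def make_table(timepoint, animals, values, variables=None):
    """Build a GaitTable from a dict/array of per-animal values."""
    values = np.asarray(values, dtype=float)
    if variables is None:
        variables = [f"v{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=variables)
    df.insert(0, "animal_id", animals)
    return GaitTable(df, timepoint)


def make_lookup(animals, groups, **extra):
    return LookupTable(pd.DataFrame({"animal_id": animals, "group": groups, **extra}))


def make_study(tables, lookup):
    return join_metadata(tables, lookup)


@pytest.fixture
def two_timepoint_study():
    """4 animals, 2 groups, 2 timepoints, 3 variables with known values."""
    animals = ["M01", "M02", "M03", "M04"]
    pre = make_table("pre", animals, [[2.0, 1.0, 4.0],
                                      [4.0, 2.0, 4.0],
                                      [2.0, 1.0, 2.0],
                                      [1.0, 2.0, 2.0]])
    post = make_table("post", animals, [[3.0, 2.0, 4.0],
                                        [6.0, 1.0, 8.0],
                                        [1.0, 1.5, 2.0],
                                        [2.0, 2.0, 1.0]])
    lookup = make_lookup(animals, ["ctrl", "ctrl", "trt", "trt"])
    return make_study([pre, post], lookup)
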