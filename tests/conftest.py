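import numpy as np
import pandas as pd
import pytest

from poreperm import DescriptorMatrix, load_descriptor_table, load_dye_panel


@pytest.fixture(scope="session")
def dye_panel():
    return load_dye_panel()


@pytest.fixture(scope="session")
def descriptor_table():
    return load_descriptor_table()


@pytest.fixture()
def small_labelled_matrix():
    """5 molecules x 3 descriptors, hand-sized for exhaustive checks."""
    frame = pd.DataFrame(
        {
            "a": [0.0, 1.0, 10.0, 11.0, 5.0],
            "b": [1.0, 2.0, 3.0, 4.0, 5.0],
            "c": [0.5, 0.4, 0.3, 0.2, 0.1],
        },
        index=["m1", "m2", "m3", "m4", "m5"],
    )
    labels = ["permeant", "permeant", "non_permeant", "non_permeant", "permeant"]
    return DescriptorMatrix(frame, labels)


def random_labelled_matrix(rng, n_molecules, n_descriptors):
    """Random labelled matrix with both classes present."""
    frame = pd.DataFrame(
        rng.normal(size=(n_molecules, n_descriptors)),
        index=[f"m{i}" for i in range(n_molecules)],
        columns=[f"d{j}" for j in range(n_descriptors)],
    )
    labels = ["permeant" if i % 2 == 0 else "non_permeant" for i in range(n_molecules)]
    return DescriptorMatrix(frame, labels)
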