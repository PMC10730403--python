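import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ironsig.io_formats import CellAnnotation, CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_counts():
    """4 genes x 3 cells with a mitochondrial and a ribosomal gene."""
    values = sp.csr_matrix(
        np.array(
            [
                [5, 0, 2],
                [1, 3, 0],
                [2, 1, 1],
                [0, 4, 1],
            ]
        )
    )
    return CountMatrix(values, ["Fth1", "Ftl1", "mt-Nd1", "Rps1"], ["c1", "c2", "c3"])


def make_annotation(cell_ids, cell_types=None, conditions=None, donors=None, studies=None):
    n = len(cell_ids)
    return CellAnnotation(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "cell_type_level1": cell_types or ["typeA"] * n,
                "condition": conditions or ["control"] * n,
                "donor_id": donors or ["d1"] * n,
                "study_id": studies or ["s1"] * n,
            }
        )
    )


@pytest.fixture
def annotation_factory():
    return make_annotation
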