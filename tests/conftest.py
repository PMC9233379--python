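import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from spatclust.core import BlockGroupSet


def lattice_blocks(n_rows: int, n_cols: int, cell: float = 1.0) -> BlockGroupSet:
    """Plain square lattice with unit populations (planar coordinates)."""
    ids, geoms = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            ids.append(f"b{r:03d}{c:03d}")
            geoms.append(box(c * cell, r * cell, (c + 1) * cell, (r + 1) * cell))
    data = pd.DataFrame({"adult_population": 1000},
                        index=pd.Index(ids, name="block_id"))
    return BlockGroupSet(ids=ids, geometries=geoms, data=data)


@pytest.fixture
def unit_square():
    return box(0.0, 0.0, 1.0, 1.0)


@pytest.fixture
def l_shape():
    # unit square with the top-right quarter removed
    return Polygon([(0, 0), (1, 0), (1, 0.5), (0.5, 0.5), (0.5, 1), (0, 1)])


@pytest.fixture
def lattice_3x3():
    return lattice_blocks(3, 3)


@pytest.fixture
def lattice_10x10():
    return lattice_blocks(10, 10)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
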