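"""Shared fixtures: a small fictive four-individual dataset and helpers.

The ``fictive_columns`` fixture encodes the canonical worked example for
homo-quartet analysis: four individuals, five positions, individual ind1
carrying a homo-quartet at every position.  Positions 1-2 are monoallelic
(they inform on the error pattern), positions 3-5 are biallelic; at
position 3 the ind1 minor state (G) differs from the other segregating
allele (C), while at positions 4 and 5 it coincides with it (T).  The
grouping fixture splits individuals into two shipment batches such that
position 4 is polymorphic *within* ind1's batch (excluded from the
between-batch index) while position 5 is not (retained).
"""

import numpy as np
import pytest
from hypothesis import settings

from contamkit.quartets import SiteColumn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

INDIVIDUALS = ["ind1", "ind2", "ind3", "ind4"]


def _col(position, rows):
    return SiteColumn(
        contig="contig1",
        position=position,
        individuals=INDIVIDUALS,
        counts=np.array(rows, dtype=np.int64),
    )


@pytest.fixture(scope="session")
def fictive_columns():
    # counts are (A, C, G, T) per individual
    return [
        # pos 0: monoallelic, ind1 minor T
        _col(0, [[45, 0, 0, 1], [50, 0, 0, 0], [50, 0, 0, 0], [50, 0, 0, 0]]),
        # pos 1: monoallelic, ind1 minor C
        _col(1, [[45, 1, 0, 0], [50, 0, 0, 0], [50, 0, 0, 0], [50, 0, 0, 0]]),
        # pos 2: biallelic (A/C segregate), ind1 minor G != z
        _col(2, [[45, 0, 1, 0], [25, 25, 0, 0], [0, 50, 0, 0], [50, 0, 0, 0]]),
        # pos 3: biallelic (A/T), ind1 minor T == z; T present inside both batches
        _col(3, [[45, 0, 0, 1], [24, 0, 0, 26], [0, 0, 0, 50], [50, 0, 0, 0]]),
        # pos 4: biallelic (A/T), ind1 minor T == z; T only in the other batch
        _col(4, [[45, 0, 0, 1], [50, 0, 0, 0], [0, 0, 0, 50], [25, 0, 0, 25]]),
    ]


@pytest.fixture(scope="session")
def shipment_groups():
    return {"ind1": "batch1", "ind2": "batch1", "ind3": "batch2", "ind4": "batch2"}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
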