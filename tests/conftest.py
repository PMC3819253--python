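import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))

import numpy as np
import pytest

from kirfam.records import Alignment, Transcript
from kirfam.simulate import SimulationParams, simulate_family


@pytest.fixture(scope="session")
def family():
    """One synthetic 10-locus family reused by several test modules."""
    return simulate_family(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def family_models(family):
    return {m.locus: m for m in family.models}


def random_alignment(rng: np.random.Generator, n: int, L: int,
                     gap_fraction: float = 0.0) -> Alignment:
    chars = np.array(list("ACGT"))
    rows = chars[rng.integers(0, 4, size=(n, L))]
    if gap_fraction > 0:
        mask = rng.random((n, L)) < gap_fraction
        rows[mask] = "-"
    return Alignment(
        [Transcript(id=f"S{i}", sequence="".join(r)) for i, r in
         enumerate(rows)]
    )
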