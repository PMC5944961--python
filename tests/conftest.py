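from pathlib import Path

import numpy as np
import pytest

from sadoctave import AbundanceRecord, LayerDataset, OctaveHistogram

#: location where a user can drop the Dinghushan field table to run the
#: reproduction tests (long format: community,layer,species,abundance)
FIELD_DATA = Path(__file__).resolve().parent.parent / "data" / "dinghushan.csv"


def make_dataset(abundances, community="test", layer="layer"):
    records = [
        AbundanceRecord(f"sp{i:03d}", int(a)) for i, a in enumerate(abundances, 1)
    ]
    return LayerDataset(community, layer, records)


@pytest.fixture
def small_dataset():
    return make_dataset([1, 1, 2, 3, 5])


@pytest.fixture
def hollow_histogram():
    """A realistic hollow-curve octave histogram (many rare, few common)."""
    return OctaveHistogram(
        np.arange(1, 9), [30.0, 18.0, 11.0, 6.0, 4.0, 2.0, 1.0, 1.0], "halfopen"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20180510)
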