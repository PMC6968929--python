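import numpy as np
import pytest
from hypothesis import settings

from pyrclone.lineage import LayerCounts, Lineage

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_lineage(l23=0, l4=0, l5=0, l6=0, id="L", method="genetic", area="S1",
                 age="P21", **kwargs):
    return Lineage(
        id=id, method=method, area=area, age=age,
        counts=LayerCounts(l23=l23, l4=l4, l5=l5, l6=l6), **kwargs
    )


@pytest.fixture
def small_dataset():
    """Six hand-written lineages covering all three laminar classes."""
    return [
        make_lineage(2, 1, 2, 3, id="L1"),
        make_lineage(0, 0, 2, 3, id="L2"),
        make_lineage(3, 2, 0, 0, id="L3"),
        make_lineage(1, 1, 1, 1, id="L4"),
        make_lineage(4, 0, 0, 1, id="L5"),
        make_lineage(0, 1, 3, 0, id="L6"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
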