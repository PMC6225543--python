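import numpy as np
import pytest

from denitflux.trflp import AlignParams, Peak, Profile


@pytest.fixture
def params():
    return AlignParams(seed=0)


@pytest.fixture
def toy_profile():
    peaks = [Peak(100.0, 0.2, 0.1), Peak(150.0, 0.5, 0.6), Peak(200.0, 0.3, 0.3)]
    return Profile("S00", "nirK", "HaeIII", peaks, normalized=True)


def make_profile(sample_id, sizes, areas=None, heights=None, normalized=False, gene="nirK", enzyme="HaeIII"):
    sizes = list(sizes)
    areas = areas if areas is not None else [1.0] * len(sizes)
    heights = heights if heights is not None else [0.8 * a for a in areas]
    peaks = [Peak(s, a, h) for s, a, h in zip(sizes, areas, heights)]
    return Profile(sample_id, gene, enzyme, peaks, normalized=normalized)
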