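import numpy as np
import pandas as pd
import pytest

from atlasmap import (
    SyntheticSpec,
    anchor_annotations,
    gen_label_volume,
    generate,
)


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def truth(spec):
    """Full synthetic experiment (points + virtual sections), default seed."""
    return generate(spec)


@pytest.fixture(scope="session")
def toy_volume(spec):
    return gen_label_volume(spec)


@pytest.fixture(scope="session")
def anchored(truth, spec):
    """Points recovered by re-anchoring the synthetic annotations."""
    return anchor_annotations(truth.anchors, truth.annotations, grid_shape=spec.grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_points(rng, n=40, lo=0.0, hi=30.0):
    return rng.uniform(lo, hi, size=(n, 3))


@pytest.fixture()
def point_table(rng):
    """Small labelled point table spanning two animals."""
    xyz = rng.uniform(2, 28, size=(30, 3))
    return pd.DataFrame(
        {
            "animal_id": ["A1"] * 15 + ["A2"] * 15,
            "class": ["input"] * 30,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )
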