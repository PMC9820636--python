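import numpy as np
import pytest

from colonyqc.image import BAD, GOOD, ColonyImage, LabeledDataset
from colonyqc.synth import GeneratorParams, generate_dataset


@pytest.fixture(scope="session")
def small_params():
    """Fast renderer settings: 64 px field, whole 290 µm field of view."""
    return GeneratorParams(image_size_px=(64, 64), um_per_px=290.0 / 64.0)


@pytest.fixture(scope="session")
def tiny_dataset(small_params):
    """20 labelled synthetic colonies at full class separation."""
    return generate_dataset(10, 10, small_params, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_flat_dataset(n_good, n_bad, side=1):
    """Dataset of constant images — cheap split/count bookkeeping material."""
    items = []
    for i in range(n_good + n_bad):
        label = GOOD if i < n_good else BAD
        items.append(ColonyImage(pixels=np.full((side, side), 0.5),
                                 label=label, source_id=f"flat-{i}"))
    return LabeledDataset(items=items)
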