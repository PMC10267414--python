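import numpy as np
import pytest

from octseg.network import NetworkConfig
from octseg.phantom import PhantomConfig, generate_dataset


#: widths small enough that every test model trains/runs in seconds
MICRO_NET = NetworkConfig(stage_widths=(4, 4, 8, 8), stage_depths=(1, 1, 1, 1),
                          n_classes=9)


@pytest.fixture(scope="session")
def desk_phantoms():
    """A small, session-shared phantom dataset (64x96, 9 classes)."""
    cfg = PhantomConfig.desk_scale(64, 96, seed=11)
    samples, split = generate_dataset(cfg, 12, seed=11)
    ids = {sid: i for i, sid in enumerate(split.all_ids)}
    return {
        "config": cfg,
        "samples": samples,
        "split": split,
        "train": [samples[ids[s]] for s in split.train],
        "val": [samples[ids[s]] for s in split.val],
        "test": [samples[ids[s]] for s in split.test],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape, n_classes):
    return rng.integers(0, n_classes, size=shape)
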