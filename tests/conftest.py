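import numpy as np
import pytest
from hypothesis import settings

from hipseg import models, phantom, training

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def normal_phantom():
    """One deterministic normal-hip phantom shared across tests."""
    spec = phantom.PhantomSpec(seed=7)
    ct, lab = phantom.generate_phantom(spec)
    return spec, ct, lab


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """A small 32x32-slice network configuration for fast training tests."""
    return models.NetworkConfig(in_rows=32, in_cols=16, base_channels=4, seed=0)


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_net_cfg):
    """A lightly trained pipeline on three small phantoms, for smoke tests
    that need plausible (not accurate) weights."""
    cases = [
        (ct, lab)
        for _, _, ct, lab in phantom.generate_cases(
            3, ["normal", "OA", "FNF"], base_seed=3, shape=(32, 32, 32)
        )
    ]
    samples = training.make_half_dataset(cases, 32, 16, slice_step=2)
    cfg = training.TrainConfig(epochs=3, batch_size=16, seed=0)
    handles = {
        st: training.train_stage(st, samples, cfg, tiny_net_cfg)[0]
        for st in training.STAGES
    }
    return training.assemble(
        handles["upward"], handles["main"], handles["classifier"]
    )


def random_blob_mask(rng, shape, n_seeds=3):
    """Random connected-ish blob mask for metric fixtures."""
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        c = [rng.integers(0, s) for s in shape]
        r = rng.integers(1, max(2, min(shape) // 2))
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        mask |= d2 <= r ** 2
    return mask
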