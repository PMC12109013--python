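import logging

import numpy as np
import pytest

from ki67gan import metrics, synthdata

# the renderer logs expected clamp warnings for extreme requested indices
logging.getLogger("ki67gan.synthdata").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_pairs():
    """Sixty clean pairs with evenly spread Ki67 indices (shared, read-only)."""
    gen = np.random.default_rng(123)
    return [
        synthdata.render_patch_pair(p, size=64, rng=gen, patch_id=f"s{i:03d}")
        for i, p in enumerate(np.linspace(0.0, 0.6, 60))
    ]


@pytest.fixture(scope="session")
def desk_run():
    """Desk-scale conditional GAN training: 2,000 imbalanced-label pairs at
    64x64, 50 kimgs, gamma 2, seeded.  Shared by the end-to-end tests."""
    from ki67gan import cgan

    pairs = synthdata.make_dataset(2000, size=64, seed=11)
    images = np.stack([p.he_image for p in pairs])
    labels = np.array([p.true_index for p in pairs])
    config = cgan.TrainingConfig(total_kimgs=50.0, batch_size=32, seed=1,
                                 metric_interval_kimgs=10.0)
    checkpoint, metric_log = cgan.train((images, labels), config)
    return checkpoint, metric_log


@pytest.fixture(scope="session")
def hist_embedder():
    """Histological embedder trained on a small synthetic set (shared)."""
    pairs = synthdata.make_dataset(400, size=64, seed=21)
    images = np.stack([p.he_image for p in pairs])
    labels = np.array([p.true_index for p in pairs])
    return metrics.train_histological_embedder((images, labels),
                                               seed=0, epochs=10)
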