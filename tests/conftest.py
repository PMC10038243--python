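"""Shared fixtures: one small generated image dataset and one Gaussian
embedding set, reused across test modules (session-scoped for speed)."""

import numpy as np
import pytest

from xtalcurate import embedding, synthetic
from xtalcurate.manifest import get_preset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """80-image MARCO-preset dataset in 4-image timecourses, plus embeddings."""
    out = tmp_path_factory.mktemp("smallds")
    cfg = synthetic.SynthConfig(
        n_images=80,
        class_dist=get_preset("marco"),
        duplicate_group_size=4,
        duplicate_jitter=0.01,
        seed=11,
    )
    m = synthetic.generate_dataset(cfg, out)
    e = embedding.baseline_embed(m)
    return m, e, out


@pytest.fixture(scope="session")
def gauss4():
    """Well-separated four-class Gaussian embeddings with integer labels."""
    cfg = synthetic.EmbeddingSynthConfig(
        n_per_class=100, dim=8, class_separation=6.0, within_sd=1.0, seed=5
    )
    e, labels, sources = synthetic.generate_embeddings(cfg)
    return e, labels, sources


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
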