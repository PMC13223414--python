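import numpy as np
import pytest

from koadet.config import tiny_config
from koadet.model import KneeDetector
from koadet.phantom import generate_samples


@pytest.fixture()
def tiny_cfg():
    return tiny_config(0)


@pytest.fixture(scope="session")
def session_tiny_model():
    return KneeDetector(tiny_config(0))


@pytest.fixture(scope="session")
def phantom_batch():
    cfg = tiny_config(0)
    cfg.phantom.samples_per_grade = 4
    return generate_samples(cfg.phantom)


@pytest.fixture(scope="session")
def head_outputs(session_tiny_model, phantom_batch):
    """Eval-mode head outputs on one phantom (shared, read-only)."""
    model = session_tiny_model
    model.eval()
    from koadet import nn

    with nn.no_grad():
        return model.forward(model.prepare_image(phantom_batch[0].pixels))


def random_box(rng, lo=0.0, hi=20.0, min_size=0.5):
    x1 = rng.uniform(lo, hi - min_size)
    y1 = rng.uniform(lo, hi - min_size)
    w = rng.uniform(min_size, (hi - x1))
    h = rng.uniform(min_size, (hi - y1))
    return x1, y1, x1 + w, y1 + h
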