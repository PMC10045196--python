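"""Shared fixtures: small synthetic datasets and trained detectors.

The expensive fixtures are session-scoped so training happens once per
test run: ``mini_model`` is a narrow network trained briefly (enough to
find bright foci reliably) and ``benchmark`` is the full desk-scale
training run used by the end-to-end accuracy tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from centriodet import spot_model
from centriodet.data import max_project
from centriodet.simulate import SyntheticSpec, generate_field


def make_foci_fields(n: int, seed0: int = 1000, **spec_kwargs):
    """Nucleus-free foci fields as (plane, truth points) pairs."""
    out = []
    for i in range(n):
        spec = SyntheticSpec(n_nuclei=0, seed=seed0 + i, **spec_kwargs)
        field, foci, _ = generate_field(spec)
        out.append((max_project(field).planes[1], foci.points))
    return out


@pytest.fixture(scope="session")
def mini_model():
    """A quickly trained narrow detector: adequate for bright isolated
    foci, used where tests need *a* working model rather than the most
    accurate one."""
    items = make_foci_fields(30, seed0=500)
    cfg = spot_model.SpotModelConfig(depth=3, base_filters=8, patch_size=128,
                                     epochs=14, seed=7)
    model = spot_model.build_model(cfg)
    spot_model.train_on_arrays(model, items, cfg)
    return model


@pytest.fixture(scope="session")
def benchmark():
    """Desk-scale study conditions: 200 nucleus-free 256-px fields with
    2-8 foci pairs each, 90/10 split, and the depth-3 multiscale
    detector trained on 64-px random crops for 110 epochs with the
    late learning-rate decay and weight averaging the package uses for
    single-image-step training. Returns (model, held-out items)."""
    fields = make_foci_fields(200, seed0=1000)
    train_items, test_items = fields[:180], fields[180:]
    cfg = spot_model.SpotModelConfig(depth=3, base_filters=16, patch_size=64,
                                     epochs=110, seed=42, augment=False,
                                     lr_schedule="linear_decay", ema_decay=0.999)
    model = spot_model.build_model(cfg)
    spot_model.train_on_arrays(model, train_items, cfg)
    return model, test_items


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
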