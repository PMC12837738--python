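import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import seasight as ss
from seasight.color_index import IndexKind

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noise_free_spec():
    """Scene conditions with all stochastic degradations switched off."""
    return ss.SceneSpec(noise_sigma=0.0, blur_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def calibrated_thresholds(noise_free_spec):
    """Thresholds calibrated on six flat synthetic patches per class."""
    sets = {
        c: ss.generate_class_patches(c, 6, noise_free_spec, seed=11)
        for c in ("land", "animal", "sky")
    }
    rep = ss.calibrate(sets["land"], sets["animal"], sets["sky"])
    return rep.thresholds[IndexKind.NGMR], rep.thresholds[IndexKind.NBMG]


@pytest.fixture(scope="session")
def class_model(noise_free_spec):
    """Descriptor model trained on ten ROI-style patches per class."""
    sets = {
        c: ss.generate_class_patches(c, 10, noise_free_spec, seed=21, style="roi")
        for c in ("land", "animal", "sky")
    }
    return ss.train_class_model(sets["land"], sets["animal"], sets["sky"])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
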