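import numpy as np
import pytest
import scipy.ndimage as ndi

import cardiokin as ck
from cardiokin.evaluation import PipelineConfig, prepare_cohort


@pytest.fixture(scope="session")
def textured_image():
    """Smooth random texture: enough gradient structure for optical flow."""
    rng = np.random.default_rng(42)
    img = ndi.gaussian_filter(rng.random((64, 64)), 2.0)
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo)


@pytest.fixture(scope="session")
def reduced_config():
    return PipelineConfig.reduced()


@pytest.fixture(scope="session")
def toy_training(reduced_config):
    """N-vs-DCM phantom div-channel stacks plus a model trained on them.

    The two classes differ strongly in geometry and contraction
    amplitude, so the task is separable; shared across model-level tests
    to keep the suite fast.
    """
    cohort = [s for s in ck.generate_cohort(8, seed=11)
              if s.label in ("N", "DCM")]
    cfg = PipelineConfig.reduced(channels=("div",))
    samples = prepare_cohort(cohort, cfg)
    stacks = [s.stacks["div"] for s in samples]
    spec = ck.build_architecture(
        in_channels=1, n_classes=2, input_shape=stacks[0].shape[:3],
        filters=cfg.filters, dense_units=cfg.dense_units)
    model = ck.train_binary(stacks, config=ck.TrainConfig(epochs=20),
                            seed=0, spec=spec)
    return stacks, model
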