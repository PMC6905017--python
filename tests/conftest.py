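import numpy as np
import pytest

from rootmorph import morphometry, preprocess, synthetic


@pytest.fixture(scope="session")
def suite():
    """Canonical synthetic fixtures, rendered once per session."""
    return synthetic.fixture_suite(seed=0)


@pytest.fixture(scope="session")
def fixture_cal():
    return morphometry.PixelCalibration(synthetic._FIXTURE_PITCH)


@pytest.fixture(scope="session")
def measured(suite, fixture_cal):
    """name -> (spec, ground truth, mask, threshold result, measurements)
    for every canonical fixture, run through the full pipeline once."""
    out = {}
    for name, (spec, img, gt) in suite.items():
        mask, tres = preprocess.preprocess_pipeline(img)
        meas = morphometry.measure_root(mask, fixture_cal)
        out[name] = (spec, gt, mask, tres, meas)
    return out


def random_mask(rng: np.random.Generator, shape=(32, 32), p=0.4) -> np.ndarray:
    return rng.random(shape) < p
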