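import numpy as np
import pytest

from sowtherm import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)


@pytest.fixture(scope="session")
def clean_records():
    """Noise-free, outlier-free records for deterministic checks."""
    config = synthetic.GeneratorConfig(
        n=200, seed=7, sensor_noise_at_c=0.0, sensor_noise_rh_pct=0.0,
        ir_noise_c=0.0, outlier_fraction=0.0)
    return synthetic.generate_samples(config), config


def records_xy(records):
    frame = synthetic.records_to_frame(records)
    X = frame.loc[:, list(synthetic.FEATURE_COLUMNS)].to_numpy(float)
    y = frame[synthetic.TARGET_COLUMN].to_numpy(float)
    return X, y
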