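import numpy as np
import pytest

from dsrunet.preprocess import PreprocessConfig, preprocess_records
from dsrunet.synth import SynthConfig, generate_dataset, generate_record


CLEAN = dict(drift_amp=0.0, spike_rate_per_min=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_record():
    """One 120 s artifact-free synthetic record with ground truth."""
    cfg = SynthConfig(duration_s=120.0, seed=42, **CLEAN)
    return generate_record(cfg, np.random.default_rng(42), record_id="clean#0")


@pytest.fixture(scope="session")
def small_splits():
    """A small preprocessed synthetic dataset (train/val/test segments)."""
    scfg = SynthConfig(n_records=3, duration_s=500.0, seed=7)
    rs, _ = generate_dataset(scfg)
    splits, attrs = preprocess_records(rs, PreprocessConfig(seed=7))
    return splits, attrs
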