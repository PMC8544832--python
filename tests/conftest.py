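import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from ssvep_gain import (
    DesignSpec,
    GainParams,
    GroundTruth,
    SuppressionWeights,
    simulate_crf_table,
)
from ssvep_gain.inference import SamplerConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def std_params():
    return GainParams(r_max=5.0, p=2.0, z=100.0)


@pytest.fixture
def small_sampler():
    """Economical sampler settings for structural (non-recovery) tests."""
    return SamplerConfig(chains=2, warmup=300, draws=200, seed=0)


@pytest.fixture
def contrast_gain_dataset():
    """12-unit table with pure contrast-gain truth and its true baselines."""
    truth = GroundTruth(
        weights={"monocular": SuppressionWeights(r=1.0, g=3.0)}, weight_jitter=0.0
    )
    design = DesignSpec(mask_types=("monocular",), sweep_mask_contrasts=(), n_units=12)
    table, record = simulate_crf_table(truth, design, seed=7)
    baselines = {u: GainParams(**record["units"][u]["gain"]) for u in record["units"]}
    return table, baselines, record
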