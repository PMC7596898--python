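import warnings

import numpy as np
import pytest

import sparsebci as sb


@pytest.fixture(scope="session")
def high_snr_epochs():
    """Small high-SNR two-class epoch set (band-filtered) plus ground truth."""
    rec, truth = sb.generate(
        sb.SimConfig(n_trials_per_class=30, noise_cov_scale=0.1, seed=5)
    )
    es = sb.bandpass(sb.segment_epochs(rec, 3.0), 8.0, 15.0)
    return es, truth


@pytest.fixture(scope="session")
def full_scale_report():
    """One full-scale pipeline comparison: 140+140 trials, strong planted
    separation, shuffled last-100 held-out split.  Shared across tests that
    assert on its accuracy/loss outputs."""
    rec, _ = sb.generate(sb.SimConfig(seed=1))
    es = sb.segment_epochs(rec, 3.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sb.compare_pipelines(es, sb.PipelineConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
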