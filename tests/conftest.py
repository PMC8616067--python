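import numpy as np
import pytest

import emgcycle as e


@pytest.fixture(scope="session")
def default_trial():
    """One default-condition synthetic trial with its ground truth."""
    cfg = e.SynthConfig(seed=7)
    session, truth = e.generate_trial(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def clean_trial():
    """Zero-jitter, high-SNR trial: the planted structure is fully visible."""
    cfg = e.SynthConfig(seed=11, timing_jitter_sd=0.0, amplitude_jitter_sd=0.0, snr_db=60.0)
    session, truth = e.generate_trial(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def clean_normalized(clean_trial):
    """Segmented, time-normalized cycles of the clean trial."""
    cfg, session, truth = clean_trial
    env = e.preprocess(session)
    bounds = e.detect_boundaries(e.composite_envelope(env), cfg.fs_hz)
    return cfg, truth, e.normalize_cycles(e.segment(env, bounds))


def planted_reference(truth, n_cycles):
    """SynergyModel built from the planted W and mean per-cycle activation."""
    H_ref = np.tile(truth.true_H_per_cycle.mean(axis=0), (1, n_cycles))
    return e.SynergyModel(
        W=truth.true_W.copy(),
        H=H_ref,
        n_phases=truth.true_W.shape[1],
        vaf=1.0,
        converged=True,
        n_iter=0,
    )
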