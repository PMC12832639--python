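import numpy as np
import pytest

import eegrisk as er


@pytest.fixture(scope="session")
def montage():
    return er.standard_1020()


@pytest.fixture(scope="session")
def templates(montage):
    return er.synth_templates(montage)


@pytest.fixture(scope="session")
def planted_recording(montage, templates):
    """A 30 s noise-free rendering with known labels (fs 500)."""
    seq = er.sample_label_sequence(
        (45.0, 45.0, 48.0, 43.0), (0.25, 0.25, 0.27, 0.23),
        duration_s=30.0, fs=500.0, seed=11)
    rec = er.render_eeg(seq, templates, montage, noise_sd=0.0, seed=12,
                        subject_id="planted")
    return rec, seq


@pytest.fixture(scope="session")
def tiny_cohort(montage):
    """8-subject strong-effect cohort with fast extraction settings."""
    spec = er.strong_effect_cohort_spec(
        n_per_group=(4, 4), duration_s=20.0, fs=250.0, seed=5)
    return er.simulate_cohort(spec, montage)


def rng(seed=0):
    return np.random.default_rng(seed)
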