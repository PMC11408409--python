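import numpy as np
import pytest

from p300id import (
    P300Window, SynthConfig, build_bspline_bank, build_feature_table,
    generate_cohort, run_pipeline,
)
from p300id.synthcohort import EpochSet


@pytest.fixture(scope="session")
def bank():
    return build_bspline_bank()


def make_epochs(data, fs=250.0, t0=-200.0, groups=None, subjects=None):
    """Wrap a raw (epochs, channels, samples) array as an EpochSet."""
    data = np.asarray(data, dtype=float)
    n_ep, n_ch, n_s = data.shape
    times = t0 + np.arange(n_s) * 1000.0 / fs
    return EpochSet(
        data=data,
        times=times,
        fs=fs,
        stimulus_code=np.full(n_ep, "S2-addiction"),
        group=np.array(groups) if groups is not None else np.full(n_ep, "MA"),
        subject_id=np.array(subjects) if subjects is not None else np.full(n_ep, "s0"),
        channel_names=tuple(f"ch{i:02d}" for i in range(n_ch)),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """4+4 subjects x 10 epochs x 6 channels; quick to generate."""
    cfg = SynthConfig(
        n_subjects_ma=4, n_subjects_hc=4, epochs_per_subject=10, n_channels=6, seed=11
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-mirroring cohort (18+22 subjects, 62 channels)."""
    return generate_cohort(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    """Feature table of the preprocessed, class-balanced default cohort."""
    avg = run_pipeline(default_cohort)
    return build_feature_table(avg, P300Window())
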