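import numpy as np
import pytest

from neuromon import qeeg, synth


@pytest.fixture(scope="session")
def balanced_eeg():
    """60-s symmetric recording with equal band fractions."""
    spec = synth.EEGGenSpec(target_relative_powers=(0.25, 0.25, 0.25, 0.25),
                            duration=60.0, seed=101)
    return synth.gen_eeg(spec)


@pytest.fixture(scope="session")
def nonsurvivor_eeg():
    """60-s recording with the nonsurvivor-median band profile."""
    t = np.array([0.744, 0.084, 0.095, 0.064])
    t = t / t.sum()
    spec = synth.EEGGenSpec(target_relative_powers=tuple(t),
                            duration=60.0, seed=202)
    return synth.gen_eeg(spec)


@pytest.fixture(scope="session")
def clean_envelope():
    """Noiseless 30-s envelope, vs=60, vd=30, 72 bpm."""
    return synth.gen_tcd(synth.TCDGenSpec(vs=60.0, vd=30.0, duration=30.0,
                                          seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibrated cohort at the study's group sizes."""
    return synth.gen_cohort(synth.default_cohort_spec(seed=42))


@pytest.fixture
def toy_spectrum():
    """2-pair, 4-bin spectrum for hand-checking the symmetry index."""
    freqs = np.array([1.0, 2.0, 3.0, 4.0])
    # channels: R1, L1, R2, L2
    power = np.array([
        [4.0, 2.0, 1.0, 3.0],   # R1
        [2.0, 2.0, 3.0, 1.0],   # L1
        [1.0, 5.0, 2.0, 2.0],   # R2
        [3.0, 1.0, 2.0, 6.0],   # L2
    ])
    return qeeg.PowerSpectrum(freqs=freqs, power=power,
                              channel_labels=["R1", "L1", "R2", "L2"],
                              resolution=1.0)
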