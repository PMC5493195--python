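import numpy as np
import pytest

from tremorstability import (
    TremorAxisSignal,
    TriaxialRecording,
    Units,
    feature_table,
    generate_cohort,
    preset_cohort_spec,
)
from tremorstability.preprocess import AxisProvenance

COHORT_SEED = 1  # root seed of the shared synthetic test cohort


def make_axis_signal(freq_hz=5.0, fs=128.0, duration_s=30.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return TremorAxisSignal(
        values=amplitude * np.sin(2 * np.pi * freq_hz * t + phase),
        fs=fs,
        provenance=AxisProvenance.PC1,
    )


def make_triaxial_sinusoid(
    freq_hz=5.0,
    fs=128.0,
    duration_s=30.0,
    amplitude=20.0,
    direction=(0.6, 0.5, 0.62),
    noise_sd=0.0,
    seed=0,
):
    t = np.arange(int(duration_s * fs)) / fs
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    samples = d[:, None] * (amplitude * np.sin(2 * np.pi * freq_hz * t))[None, :]
    if noise_sd > 0:
        samples = samples + np.random.default_rng(seed).normal(0, noise_sd, samples.shape)
    return TriaxialRecording(samples=samples, fs=fs, units=Units.MG)


@pytest.fixture(scope="session")
def paper_cohort():
    """Synthetic 16 PD / 20 ET cohort emulating the published test cohort."""
    return generate_cohort(preset_cohort_spec("paper-test-cohort", seed=COHORT_SEED))


@pytest.fixture(scope="session")
def paper_features(paper_cohort):
    return feature_table((rec, label) for rec, label, _ in paper_cohort)
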