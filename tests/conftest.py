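import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from spastiq.kinematic import reconstruct_acceleration
from spastiq.preprocess import PreprocessedTrial, preprocess_trial
from spastiq.synthetic import SimSubjectParams, simulate_session


def make_constant_jerk_trial(t1=1.0, t2=1.0, acc1=4000.0, fs=100.0,
                             trial_id="cj") -> PreprocessedTrial:
    """A noise-free preprocessed trial whose speed is exactly constant-jerk."""
    acc = reconstruct_acceleration(t1, t2, acc1, fs)
    speed = cumulative_trapezoid(acc, dx=1.0 / fs, initial=0.0)
    n = len(speed)
    return PreprocessedTrial(
        subject_id="sim",
        trial_id=trial_id,
        emg_f=np.zeros(int(n * 10)),
        speed=speed,
        fs_emg=fs * 10,
        fs_gyro=fs,
        move_on=0,
        move_off=n - 1,
        emg_onset=None,
        mean_speed=float(speed.mean()),
        stretch_duration=(n - 1) / fs,
        qc_pass=True,
        qc_reason="ok",
    )


@pytest.fixture(scope="session")
def spastic_params() -> SimSubjectParams:
    return SimSubjectParams(
        subject_id="P1",
        mas_grade="1+",
        tsrt_true=55.0,
        dsrt_slope=-0.25,
        perturb_gain=0.15,
        emg_burst_amp=0.2,
        baseline_sd=0.01,
        dsrt_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def spastic_session(spastic_params):
    """One preprocessed spastic session (12 trials, deterministic)."""
    rng = np.random.default_rng(2024)
    trials = simulate_session(spastic_params, 12, rng)
    return [preprocess_trial(t) for t in trials]
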