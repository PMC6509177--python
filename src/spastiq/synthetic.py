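"""Synthetic passive-stretch cohort generator.

Emulates the study conditions the assessment framework assumes: sessions of
15-20 passive elbow stretches at experimenter-varied velocities, each trial
3-7 s long with a stretch range of 120-140 degrees, one sEMG channel at
1 kHz and one 3-axis gyroscope at 100 Hz.  Two disease signatures are built
in, matching the premises of the two biomarker models:

* the stretch reflex fires once the traversed angle crosses a velocity-
  dependent threshold DSRT(v) = tsrt_true + dsrt_slope * v (dsrt_slope <= 0,
  so faster stretches trigger earlier), giving the lambda model something
  to regress; healthy subjects never fire below a high velocity threshold;
* the intended motion is constant-jerk (triangular acceleration), and
  severity adds band-limited (2-15 Hz) acceleration fluctuations whose
  amplitude grows with the clinical grade, degrading the kinematic model's
  curve-similarity biomarkers and raising the acceleration median frequency.

All randomness flows from explicit seeds; the same seed reproduces a trial
or cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .preprocess import RawTrial

__all__ = [
    "SimSubjectParams",
    "SimTrialSpec",
    "SimulatedSubject",
    "REFERENCE_GRADE_TALLY",
    "GRADE_NUMERIC",
    "draw_subject_params",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
]

GRADE_NUMERIC: Mapping[str, float] = {"0": 0.0, "1": 1.0, "1+": 1.5, "2": 2.0, "3": 3.0}

#: Grade tally of the 24-subject cohort the framework was designed around
#: (8 healthy controls, 16 spastic subjects).
REFERENCE_GRADE_TALLY: Mapping[str, int] = {"0": 8, "1": 4, "1+": 6, "2": 4, "3": 2}

#: Grade-conditional parameter distributions.  ``tsrt_mean``/``tsrt_sd`` in
#: degrees; ``perturb_base`` plus a uniform jitter of width ``perturb_jitter``
#: gives the severity gain — the per-grade intervals are disjoint so the gain
#: is non-decreasing in numeric grade across any cohort.
GRADE_DISTRIBUTIONS: Mapping[str, dict] = {
    "0": dict(tsrt_mean=120.0, tsrt_sd=0.0, perturb_base=0.03, perturb_jitter=0.05),
    "1": dict(tsrt_mean=72.0, tsrt_sd=13.0, perturb_base=0.12, perturb_jitter=0.06),
    "1+": dict(tsrt_mean=55.0, tsrt_sd=13.0, perturb_base=0.20, perturb_jitter=0.06),
    "2": dict(tsrt_mean=42.0, tsrt_sd=13.0, perturb_base=0.30, perturb_jitter=0.06),
    "3": dict(tsrt_mean=28.0, tsrt_sd=10.0, perturb_base=0.42, perturb_jitter=0.06),
}

#: Healthy subjects only fire above this mean stretch speed (deg/s); the
#: protocol never reaches it.
HEALTHY_VELOCITY_THRESHOLD = 250.0


@dataclass(frozen=True)
class SimSubjectParams:
    """Latent physiology of one simulated subject.

    ``tsrt_true`` is the traversed angle (deg) at which the reflex fires at
    zero stretch velocity; ``dsrt_slope`` (deg per deg/s, <= 0) makes the
    dynamic threshold shrink with speed.  ``perturb_gain`` scales the
    severity fluctuations added to the stretch acceleration (fraction of the
    base acceleration peak).  ``dsrt_noise_sd`` jitters each trial's firing
    angle (deg).  ``min_burst_velocity`` gates the reflex entirely below
    that mean speed (used for healthy subjects).
    """

    subject_id: str
    mas_grade: str
    tsrt_true: float
    dsrt_slope: float
    perturb_gain: float
    emg_burst_amp: float = 0.15
    baseline_sd: float = 0.01
    dsrt_noise_sd: float = 3.0
    min_burst_velocity: float = 0.0
    muscle: str = "BB"

    def __post_init__(self) -> None:
        if self.mas_grade not in GRADE_NUMERIC:
            raise ValueError(f"unsupported MAS grade {self.mas_grade!r}")
        if not 0.0 < self.tsrt_true <= 120.0:
            raise ValueError("tsrt_true must lie in (0, 120] degrees")
        if self.dsrt_slope > 0.0:
            raise ValueError("dsrt_slope must be <= 0")
        if self.perturb_gain < 0.0:
            raise ValueError("perturb_gain must be >= 0")
        if self.emg_burst_amp <= 0.0 or self.baseline_sd <= 0.0:
            raise ValueError("EMG amplitudes must be positive")


@dataclass(frozen=True)
class SimTrialSpec:
    """Shape of one simulated trial.

    ``peak_velocity`` (deg/s) and ``rom`` (deg, within the 120-140 inclusion
    range) fix the stretch: with a symmetric constant-jerk profile the
    stretch lasts ``2*rom/peak_velocity`` seconds at mean speed
    ``peak_velocity/2``.  ``duration`` (s, within 3-7) is the whole trial
    including the pre-stretch rest used as detection baseline.
    """

    duration: float
    peak_velocity: float
    rom: float
    seed: int
    stretch_onset: float = 1.0

    def __post_init__(self) -> None:
        if not 3.0 <= self.duration <= 7.0:
            raise ValueError("trial duration must lie in [3, 7] s")
        if not 120.0 <= self.rom <= 140.0:
            raise ValueError("rom must lie in [120, 140] degrees")
        if self.peak_velocity <= 0.0:
            raise ValueError("peak_velocity must be positive")
        if self.stretch_onset < 0.55:
            raise ValueError("stretch_onset must leave a >=0.55 s baseline")

    @property
    def stretch_duration(self) -> float:
        return 2.0 * self.rom / self.peak_velocity

    @property
    def mean_speed(self) -> float:
        return self.peak_velocity / 2.0


@dataclass(frozen=True)
class SimulatedSubject:
    """One simulated session: latent parameters plus the recorded trials."""

    params: SimSubjectParams
    trials: tuple[RawTrial, ...]

    @property
    def mas_grade(self) -> str:
        return self.params.mas_grade


# gyroscope axis mix for the (single-axis) elbow rotation, unit norm
_AXIS = np.array([0.9, 0.35, 0.25])
_AXIS = _AXIS / np.linalg.norm(_AXIS)
# per-axis rate noise, deg/s RMS: consumer MEMS gyro noise density
# (~0.01 dps/sqrt(Hz)) over a 50 Hz bandwidth
_GYRO_NOISE_SD = 0.07


def _constant_jerk_acceleration(t: np.ndarray, t0: float, t1: float, t2: float, a1: float) -> np.ndarray:
    """Triangular (constant-jerk) acceleration: up-triangle peaking ``a1``
    over ``t1``, down-triangle peaking ``-a1*t1/t2`` over ``t2``."""
    a2 = a1 * t1 / t2
    tau = t - t0
    acc = np.zeros_like(t)
    m = (tau >= 0) & (tau < t1 / 2)
    acc[m] = a1 * tau[m] / (t1 / 2)
    m = (tau >= t1 / 2) & (tau < t1)
    acc[m] = a1 * (t1 - tau[m]) / (t1 / 2)
    m = (tau >= t1) & (tau < t1 + t2 / 2)
    acc[m] = -a2 * (tau[m] - t1) / (t2 / 2)
    m = (tau >= t1 + t2 / 2) & (tau <= t1 + t2)
    acc[m] = -a2 * (t1 + t2 - tau[m]) / (t2 / 2)
    return acc


def _band_limited_noise(n: int, fs: float, rng: np.random.Generator,
                        band: tuple[float, float] = (2.0, 15.0)) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(n)
    b, a = sps.butter(2, band, btype="bandpass", fs=fs)
    x = sps.filtfilt(b, a, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_trial(params: SimSubjectParams, spec: SimTrialSpec,
                   fs_emg: float = 1000.0, fs_gyro: float = 100.0,
                   trial_id: str = "t000") -> RawTrial:
    """Generate one raw trial; deterministic given ``spec.seed``.

    The gyroscope magnitude follows a symmetric constant-jerk stretch plus
    zero-net-velocity band-limited fluctuations of amplitude
    ``perturb_gain`` x (base acceleration peak).  The EMG is Gaussian
    baseline noise plus an amplitude-modulated 20-450 Hz burst starting when
    the traversed angle of the base profile first crosses
    ``DSRT(v) = tsrt_true + dsrt_slope * v`` (v = mean stretch speed); no
    burst is emitted if that angle exceeds the range of motion, or for
    subjects gated below ``min_burst_velocity``.
    """
    T = spec.stretch_duration
    if spec.stretch_onset + T > spec.duration - 0.2:
        raise ValueError(
            f"stretch of {T:.2f} s starting at {spec.stretch_onset:.2f} s does not "
            f"fit in a {spec.duration:.2f} s trial"
        )
    rng = np.random.default_rng(spec.seed)

    n_g = int(round(spec.duration * fs_gyro))
    t_g = np.arange(n_g) / fs_gyro
    t1 = t2 = T / 2.0
    a1 = 4.0 * spec.peak_velocity / T  # peak of the base acceleration triangle

    acc = _constant_jerk_acceleration(t_g, spec.stretch_onset, t1, t2, a1)

    if params.perturb_gain > 0:
        noise = _band_limited_noise(n_g, fs_gyro, rng)
        window = (t_g >= spec.stretch_onset) & (t_g <= spec.stretch_onset + T)
        pert = np.where(window, noise, 0.0)
        if window.any():
            pert[window] -= pert[window].mean()  # zero net velocity change
        acc = acc + params.perturb_gain * a1 * pert

    from scipy.integrate import cumulative_trapezoid

    velocity = cumulative_trapezoid(acc, t_g, initial=0.0)
    gyro = velocity[:, None] * _AXIS[None, :] + rng.normal(0.0, _GYRO_NOISE_SD, (n_g, 3))

    # EMG channel
    n_e = int(round(spec.duration * fs_emg))
    emg = rng.normal(0.0, params.baseline_sd, n_e)

    onset_time = _burst_onset_time(params, spec, rng)
    if onset_time is not None:
        i0 = int(round(onset_time * fs_emg))
        end_time = min(spec.stretch_onset + T + 0.1, spec.duration - 0.05)
        i1 = int(round(end_time * fs_emg))
        if i0 < i1 <= n_e:
            env = np.zeros(n_e)
            rise = max(1, int(round(0.05 * fs_emg)))  # 50 ms rise
            decay = max(1, int(round(0.1 * fs_emg)))
            env[i0 : min(i0 + rise, n_e)] = np.linspace(0.0, 1.0, min(rise, n_e - i0))
            env[min(i0 + rise, n_e) : i1] = 1.0
            env[i1 : min(i1 + decay, n_e)] = np.linspace(1.0, 0.0, min(decay, n_e - i1))
            burst = _band_limited_noise(n_e, fs_emg, rng, band=(20.0, 450.0))
            emg = emg + params.emg_burst_amp * env * burst

    return RawTrial(
        emg=emg,
        gyro=gyro,
        subject_id=params.subject_id,
        trial_id=trial_id,
        muscle=params.muscle,
        fs_emg=fs_emg,
        fs_gyro=fs_gyro,
    )


def _burst_onset_time(params: SimSubjectParams, spec: SimTrialSpec,
                      rng: np.random.Generator) -> float | None:
    """Time at which the reflex burst starts, or ``None`` for no burst.

    Determined by integrating the noise-free base speed profile to the
    target angle; the per-trial angle jitter (``dsrt_noise_sd``) is drawn
    whether or not a burst results, keeping the rest of the stream aligned.
    """
    v = spec.mean_speed
    jitter = rng.normal(0.0, params.dsrt_noise_sd) if params.dsrt_noise_sd > 0 else 0.0
    if v < params.min_burst_velocity:
        return None
    target = params.tsrt_true + params.dsrt_slope * v + jitter
    target = max(target, 1.0)
    if target >= spec.rom:
        return None
    # closed-form traversed angle of the symmetric constant-jerk profile,
    # solved on a fine grid (analytic inversion is piecewise quartic)
    fs = 10000.0
    tau = np.arange(int(round(spec.stretch_duration * fs)) + 1) / fs
    a1 = 4.0 * spec.peak_velocity / spec.stretch_duration
    acc = _constant_jerk_acceleration(tau, 0.0, spec.stretch_duration / 2,
                                      spec.stretch_duration / 2, a1)
    from scipy.integrate import cumulative_trapezoid

    vel = cumulative_trapezoid(acc, tau, initial=0.0)
    ang = cumulative_trapezoid(vel, tau, initial=0.0)
    idx = np.searchsorted(ang, target)
    if idx >= len(ang):
        return None
    return spec.stretch_onset + float(tau[idx])


def draw_subject_params(subject_id: str, grade: str, rng: np.random.Generator,
                        dsrt_noise_sd: float = 3.0,
                        distributions: Mapping[str, dict] | None = None) -> SimSubjectParams:
    """Draw one subject's latent parameters from the grade-conditional
    distributions (see ``GRADE_DISTRIBUTIONS``)."""
    dist = (distributions or GRADE_DISTRIBUTIONS)[grade]
    if grade == "0":
        tsrt = 120.0
        slope = 0.0
        gate = HEALTHY_VELOCITY_THRESHOLD
    else:
        tsrt = float(np.clip(rng.normal(dist["tsrt_mean"], dist["tsrt_sd"]), 10.0, 110.0))
        slope = float(rng.uniform(-0.4, -0.15))
        gate = 0.0
    gain = float(dist["perturb_base"] + rng.uniform(0.0, dist["perturb_jitter"]))
    amp = float(0.08 + 0.05 * GRADE_NUMERIC[grade] + rng.uniform(0.0, 0.03))
    base_sd = float(0.008 + rng.uniform(0.0, 0.004))
    return SimSubjectParams(
        subject_id=subject_id,
        mas_grade=grade,
        tsrt_true=tsrt,
        dsrt_slope=slope,
        perturb_gain=gain,
        emg_burst_amp=amp,
        baseline_sd=base_sd,
        dsrt_noise_sd=dsrt_noise_sd,
        min_burst_velocity=gate,
    )


def simulate_session(params: SimSubjectParams, n_trials: int,
                     rng: np.random.Generator) -> tuple[RawTrial, ...]:
    """Simulate one session of ``n_trials`` stretches spanning slow to fast.

    Peak velocities cover 60-260 deg/s (with per-trial jitter) so the DSRT
    regression is well-conditioned and several trials land in the 1-2 s
    window the kinematic model requires.
    """
    peaks = np.linspace(60.0, 260.0, n_trials) + rng.uniform(-5.0, 5.0, n_trials)
    trials = []
    for i, v in enumerate(peaks):
        rom = float(rng.uniform(120.0, 140.0))
        T = 2.0 * rom / v
        duration = float(np.clip(T + 2.0, 3.0, 7.0))
        spec = SimTrialSpec(
            duration=duration,
            peak_velocity=float(v),
            rom=rom,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        trials.append(simulate_trial(params, spec, trial_id=f"t{i:03d}"))
    return tuple(trials)


def simulate_cohort(n_subjects: int,
                    grade_distribution: Mapping[str, int] | None = None,
                    master_seed: int = 0,
                    trials_range: tuple[int, int] = (15, 20),
                    dsrt_noise_sd: float = 3.0) -> list[SimulatedSubject]:
    """Simulate a cohort; deterministic given ``master_seed``.

    ``grade_distribution`` maps grade to subject count (must sum to
    ``n_subjects``); the default uses the 24-subject reference tally scaled
    to ``n_subjects`` as closely as possible.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects (leave-one-out undefined otherwise)")
    if grade_distribution is None:
        grade_distribution = _scaled_tally(n_subjects)
    if sum(grade_distribution.values()) != n_subjects:
        raise ValueError("grade_distribution counts must sum to n_subjects")
    for g in grade_distribution:
        if g not in GRADE_NUMERIC:
            raise ValueError(f"unsupported MAS grade {g!r}")

    rng = np.random.default_rng(master_seed)
    grades = [g for g, c in grade_distribution.items() for _ in range(c)]
    cohort = []
    for i, grade in enumerate(grades):
        params = draw_subject_params(f"S{i:03d}", grade, rng, dsrt_noise_sd=dsrt_noise_sd)
        n_trials = int(rng.integers(trials_range[0], trials_range[1] + 1))
        trials = simulate_session(params, n_trials, rng)
        cohort.append(SimulatedSubject(params=params, trials=trials))
    return cohort


def _scaled_tally(n_subjects: int) -> dict[str, int]:
    """Scale the reference grade tally to ``n_subjects`` (largest remainder)."""
    total = sum(REFERENCE_GRADE_TALLY.values())
    raw = {g: c * n_subjects / total for g, c in REFERENCE_GRADE_TALLY.items()}
    out = {g: int(np.floor(v)) for g, v in raw.items()}
    short = n_subjects - sum(out.values())
    for g, _ in sorted(raw.items(), key=lambda kv: kv[1] - np.floor(kv[1]), reverse=True):
        if short <= 0:
            break
        out[g] += 1
        short -= 1
    return out
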