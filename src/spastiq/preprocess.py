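"""Signal conditioning for passive-stretch trials.

Raw trials carry one surface-EMG channel (1 kHz) and one 3-axis gyroscope
(100 Hz) recorded during a passive elbow stretch.  This module filters both
channels, collapses the gyroscope to an angular-speed magnitude, finds the
movement bounds and the EMG burst onset by amplitude thresholding against
the pre-stretch baseline, and applies automated per-trial quality control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "RawTrial",
    "PreprocessedTrial",
    "PreprocessConfig",
    "filter_emg",
    "filter_gyro",
    "angular_speed",
    "emg_envelope",
    "detect_bounds",
    "qc_trial",
    "preprocess_trial",
]


@dataclass(frozen=True)
class RawTrial:
    """One passive elbow stretch as recorded.

    ``emg`` is a single-channel surface EMG trace in mV; ``gyro`` is an
    (n, 3) array of angular rates in deg/s.  The two time bases must cover
    the same interval: ``len(emg)/fs_emg ~= len(gyro)/fs_gyro`` within one
    gyroscope sample.
    """

    emg: np.ndarray
    gyro: np.ndarray
    subject_id: str
    trial_id: str
    muscle: str = "BB"
    fs_emg: float = 1000.0
    fs_gyro: float = 100.0

    def __post_init__(self) -> None:
        emg = np.asarray(self.emg, dtype=float)
        gyro = np.asarray(self.gyro, dtype=float)
        object.__setattr__(self, "emg", emg)
        object.__setattr__(self, "gyro", gyro)
        if gyro.ndim != 2 or gyro.shape[1] != 3:
            raise ValueError("gyro must be an (n, 3) array")
        if self.muscle not in ("BB", "TB"):
            raise ValueError(f"muscle must be 'BB' or 'TB', got {self.muscle!r}")
        dur_emg = len(emg) / self.fs_emg
        dur_gyro = len(gyro) / self.fs_gyro
        if abs(dur_emg - dur_gyro) > 1.0 / self.fs_gyro + 1e-9:
            raise ValueError(
                "EMG and gyroscope durations disagree by more than one gyro "
                f"sample ({dur_emg:.3f} s vs {dur_gyro:.3f} s)"
            )


@dataclass
class PreprocessedTrial:
    """Filtered trial with detected movement bounds and EMG onset.

    ``move_on``/``move_off`` index the 100 Hz speed series; ``emg_onset``
    (when a burst was detected) indexes the 1 kHz EMG series and always maps
    to a time inside the movement window.
    """

    subject_id: str
    trial_id: str
    emg_f: np.ndarray
    speed: np.ndarray
    fs_emg: float
    fs_gyro: float
    move_on: Optional[int]
    move_off: Optional[int]
    emg_onset: Optional[int]
    mean_speed: float
    stretch_duration: float
    qc_pass: bool
    qc_reason: str
    emg_baseline_sd: float = np.nan
    clip_fraction: float = 0.0


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables for filtering, detection and QC.

    The detection threshold is ``baseline_mean + k * baseline_SD`` computed
    over the first ``baseline_window`` seconds of each channel (the rest
    before the stretch); a burst or movement is declared on the earliest run
    of at least ``min_run`` seconds above threshold.
    """

    emg_band: tuple[float, float] = (20.0, 450.0)
    emg_order: int = 4
    gyro_cutoff: float = 10.0
    gyro_order: int = 2
    baseline_window: float = 0.5
    k: float = 3.0
    min_run: float = 0.025
    move_min_run: float = 0.3
    rms_window: float = 0.05
    clip_value: float = 4.0
    clip_fraction_max: float = 0.05
    emg_baseline_sd_max: float = 0.5
    duration_range: tuple[float, float] = (0.3, 10.0)


def _zero_phase(x: np.ndarray, b: np.ndarray, a: np.ndarray) -> np.ndarray:
    order = max(len(a), len(b)) - 1
    padlen = 3 * order
    if len(x) <= padlen * 2:
        raise ValueError(
            f"series of length {len(x)} too short for zero-phase filtering "
            f"(needs more than {2 * padlen} samples)"
        )
    return sps.filtfilt(b, a, x, padlen=padlen)


def filter_emg(
    emg: np.ndarray,
    fs: float = 1000.0,
    band: tuple[float, float] = (20.0, 450.0),
    order: int = 4,
) -> np.ndarray:
    """Zero-lag Butterworth band-pass (default 4th order, 20-450 Hz).

    Applied forward and backward (``filtfilt``) so the net phase is zero;
    the effective magnitude response is the squared Butterworth response.
    """
    emg = np.asarray(emg, dtype=float)
    b, a = sps.butter(order, band, btype="bandpass", fs=fs)
    return _zero_phase(emg, b, a)


def filter_gyro(
    gyro: np.ndarray,
    fs: float = 100.0,
    cutoff: float = 10.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-lag Butterworth low-pass (default 2nd order, 10 Hz), per axis."""
    gyro = np.asarray(gyro, dtype=float)
    b, a = sps.butter(order, cutoff, btype="lowpass", fs=fs)
    if gyro.ndim == 1:
        return _zero_phase(gyro, b, a)
    return np.column_stack([_zero_phase(gyro[:, i], b, a) for i in range(gyro.shape[1])])


def angular_speed(gyro_f: np.ndarray) -> np.ndarray:
    """Angular-speed magnitude: per-sample Euclidean norm of the three axes."""
    gyro_f = np.asarray(gyro_f, dtype=float)
    return np.linalg.norm(gyro_f, axis=-1)


def emg_envelope(emg_f: np.ndarray, fs: float = 1000.0, window: float = 0.05) -> np.ndarray:
    """Detection envelope: full-wave rectification then moving RMS (50 ms)."""
    n = max(1, int(round(window * fs)))
    return np.sqrt(uniform_filter1d(np.asarray(emg_f, dtype=float) ** 2, n, mode="nearest"))


def detect_bounds(
    x: np.ndarray,
    fs: float,
    baseline_window: float = 0.5,
    k: float = 3.0,
    min_run: float = 0.025,
    baseline_sd: float | None = None,
) -> Optional[tuple[int, int]]:
    """Amplitude-threshold onset/offset detection.

    The threshold is ``mean + k * SD`` of the first ``baseline_window``
    seconds.  Returns ``(onset, offset)`` for the earliest run of at least
    ``min_run`` seconds strictly above threshold, or ``None`` when no run
    qualifies.  The same rule serves the speed channel (movement bounds) and
    the rectified-smoothed EMG envelope (burst onset; offset unused there).
    For the EMG envelope, pass ``baseline_sd`` = the SD of the baseline EMG
    *signal*: the smoothing shrinks the envelope's own baseline SD so much
    that ``k`` times it sits inside the noise and false onsets abound.
    """
    x = np.asarray(x, dtype=float)
    n_base = int(round(baseline_window * fs))
    if n_base < 1 or n_base >= len(x):
        raise ValueError(
            f"baseline window ({n_base} samples) must be shorter than the signal ({len(x)})"
        )
    baseline = x[:n_base]
    sd = baseline.std() if baseline_sd is None else baseline_sd
    thr = baseline.mean() + k * sd
    above = x > thr
    n_run = max(1, int(round(min_run * fs)))

    # earliest run of >= n_run consecutive samples above threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= n_run:
            return int(start), int(stop - 1)
    return None


def _refine_bounds(speed: np.ndarray, on: int, off: int, floor: float) -> tuple[int, int]:
    """Extend threshold-crossing movement bounds down to the noise floor.

    The amplitude threshold fires only once the speed clears the noise
    floor, clipping the slow tails of the stretch; walking each bound
    outward while the speed keeps decreasing — but stays above the baseline
    noise level ``floor`` — recovers them without swallowing baseline
    samples, so the mean speed over the window is unbiased.
    """
    while on > 0 and floor < speed[on - 1] < speed[on]:
        on -= 1
    while off < len(speed) - 1 and floor < speed[off + 1] < speed[off]:
        off += 1
    return on, off


def qc_trial(trial: PreprocessedTrial, cfg: PreprocessConfig | None = None) -> tuple[bool, str]:
    """Automated per-trial quality control; always returns a verdict.

    Failure reasons (machine-readable): ``no_movement``, ``bad_duration``,
    ``emg_saturation``, ``clipping``.
    """
    cfg = cfg or PreprocessConfig()
    if trial.move_on is None or trial.move_off is None:
        return False, "no_movement"
    lo, hi = cfg.duration_range
    if not (lo <= trial.stretch_duration <= hi):
        return False, "bad_duration"
    if np.isfinite(trial.emg_baseline_sd) and trial.emg_baseline_sd > cfg.emg_baseline_sd_max:
        return False, "emg_saturation"
    if trial.clip_fraction >= cfg.clip_fraction_max:
        return False, "clipping"
    return True, "ok"


def preprocess_trial(raw: RawTrial, cfg: PreprocessConfig | None = None) -> PreprocessedTrial:
    """Full conditioning chain for one trial.

    Filters both channels, computes the speed magnitude, detects movement
    bounds on the speed channel and the EMG burst onset on the rectified-
    smoothed EMG envelope, and attaches the QC verdict.  A detected EMG
    onset outside the movement window is discarded (set to ``None``).
    """
    cfg = cfg or PreprocessConfig()
    emg_f = filter_emg(raw.emg, raw.fs_emg, cfg.emg_band, cfg.emg_order)
    gyro_f = filter_gyro(raw.gyro, raw.fs_gyro, cfg.gyro_cutoff, cfg.gyro_order)
    speed = angular_speed(gyro_f)

    # movement must outlast move_min_run: the low-passed speed noise is
    # autocorrelated over tens of ms, so the EMG-scale min_run would let
    # noise excursions qualify as movement
    bounds = detect_bounds(speed, raw.fs_gyro, cfg.baseline_window, cfg.k, cfg.move_min_run)
    if bounds is not None:
        n_base_g = int(round(cfg.baseline_window * raw.fs_gyro))
        floor = float(speed[:n_base_g].mean() + speed[:n_base_g].std())
        move_on, move_off = _refine_bounds(speed, *bounds, floor=floor)
    else:
        move_on, move_off = None, None

    emg_onset: Optional[int] = None
    if bounds is not None:
        env = emg_envelope(emg_f, raw.fs_emg, cfg.rms_window)
        n_base = int(round(cfg.baseline_window * raw.fs_emg))
        hit = detect_bounds(
            env,
            raw.fs_emg,
            cfg.baseline_window,
            cfg.k,
            cfg.min_run,
            baseline_sd=float(np.std(emg_f[:n_base])),
        )
        if hit is not None:
            onset = hit[0]
            t = onset / raw.fs_emg
            if move_on / raw.fs_gyro <= t <= move_off / raw.fs_gyro:
                emg_onset = onset
            else:
                logger.info(
                    "trial %s: EMG onset at %.3f s outside movement window, discarded",
                    raw.trial_id,
                    t,
                )

    if bounds is not None:
        seg = speed[move_on : move_off + 1]
        mean_speed = float(seg.mean())
        stretch_duration = (move_off - move_on) / raw.fs_gyro
    else:
        mean_speed = 0.0
        stretch_duration = 0.0

    n_base = int(round(cfg.baseline_window * raw.fs_emg))
    emg_baseline_sd = float(np.std(raw.emg[:n_base])) if n_base < len(raw.emg) else np.nan
    clip_fraction = float(np.mean(np.abs(raw.emg) >= cfg.clip_value))

    trial = PreprocessedTrial(
        subject_id=raw.subject_id,
        trial_id=raw.trial_id,
        emg_f=emg_f,
        speed=speed,
        fs_emg=raw.fs_emg,
        fs_gyro=raw.fs_gyro,
        move_on=move_on,
        move_off=move_off,
        emg_onset=emg_onset,
        mean_speed=mean_speed,
        stretch_duration=stretch_duration,
        qc_pass=False,
        qc_reason="",
        emg_baseline_sd=emg_baseline_sd,
        clip_fraction=clip_fraction,
    )
    ok, reason = qc_trial(trial, cfg)
    trial.qc_pass = ok
    trial.qc_reason = reason
    if not ok:
        logger.info("trial %s failed QC: %s", raw.trial_id, reason)
    return trial
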