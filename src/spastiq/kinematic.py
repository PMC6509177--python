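"""Kinematic model: constant-jerk reconstruction and similarity biomarkers.

Passive stretches are assumed to follow a constant-jerk intended motion:
the angular acceleration is piecewise linear ("subtriangular"), one
triangle up over the accelerating stage t1 and one down over the
decelerating stage t2, balanced so the net velocity change is zero.  The
reconstructed acceleration is integrated twice to an intended angle curve,
scaled to the actual range of motion, then differentiated back so angle,
speed and acceleration stay mutually consistent.  Deviation of the actual
motion from this reference — quantified per trial by three Pearson
correlations (angle, speed, acceleration) plus the median frequency of the
actual acceleration — indexes the mechanical component of spasticity.
Only trials whose stretch lasts 1-2 s enter the per-subject biomarkers, to
limit velocity variation from the manual stretch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import periodogram

from .preprocess import PreprocessedTrial

logger = logging.getLogger(__name__)

__all__ = [
    "ReconstructionResult",
    "KinematicBiomarkers",
    "DEFAULT_ACC1",
    "split_phases",
    "reconstruct_acceleration",
    "reconstruct_kinematics",
    "median_frequency",
    "extract_kinematic_biomarkers",
]

#: Default first-stage acceleration peak, deg/s^2.
DEFAULT_ACC1 = 4000.0


@dataclass
class ReconstructionResult:
    """Constant-jerk reconstruction of one stretch.

    ``acc2 = acc1 * t1 / t2`` exactly (areas balance, zero net velocity);
    ``scale_factor`` maps the unscaled double integral onto the actual range
    of motion.  The three ``recon_*`` series live on the trial's 100 Hz time
    base over the stretch window.
    """

    t1: float
    t2: float
    tmax_index: int
    acc1: float
    acc2: float
    recon_angle: np.ndarray
    recon_speed: np.ndarray
    recon_acc: np.ndarray
    scale_factor: float


@dataclass
class KinematicBiomarkers:
    """Per-subject kinematic biomarkers, averaged over eligible trials."""

    corr_angle: float
    corr_speed: float
    corr_acc: float
    mdf_acc: float
    n_trials_used: int

    def summary(self) -> str:
        lines = [
            "Kinematic-model biomarkers",
            "=" * 38,
            f"{'corr(angle)':<24}{self.corr_angle:>12.4f}",
            f"{'corr(speed)':<24}{self.corr_speed:>12.4f}",
            f"{'corr(acceleration)':<24}{self.corr_acc:>12.4f}",
            f"{'MDF(acceleration)':<24}{self.mdf_acc:>10.3f} Hz",
            f"{'trials used':<24}{self.n_trials_used:>12d}",
        ]
        return "\n".join(lines)

    def to_record(self, subject_id: str = "") -> dict:
        return {
            "subject_id": subject_id,
            "corr_angle": float(self.corr_angle),
            "corr_speed": float(self.corr_speed),
            "corr_acc": float(self.corr_acc),
            "mdf_acc": float(self.mdf_acc),
            "n_trials_used": int(self.n_trials_used),
        }


def split_phases(
    speed: np.ndarray, move_on: int, move_off: int, fs: float = 100.0
) -> tuple[int, float, float]:
    """Split the stretch at the speed maximum.

    Returns ``(tmax_index, t1, t2)``: the (earliest, on ties) index of the
    maximal speed within [move_on, move_off] on the full-series time base,
    the accelerating-stage duration t1 and the decelerating-stage t2 in
    seconds.  ``t1 + t2`` equals the stretch duration by construction.
    """
    if move_off <= move_on:
        raise ValueError("move_off must exceed move_on")
    window = np.asarray(speed, dtype=float)[move_on : move_off + 1]
    tmax_index = move_on + int(np.argmax(window))  # argmax takes the earliest maximum
    t1 = (tmax_index - move_on) / fs
    t2 = (move_off - tmax_index) / fs
    return tmax_index, t1, t2


def reconstruct_acceleration(
    t1: float, t2: float, acc1: float = DEFAULT_ACC1, fs: float = 100.0
) -> np.ndarray:
    """Subtriangular (constant-jerk) acceleration over t1 + t2 seconds.

    An isoceles triangle rising to ``acc1`` over t1 is followed by one
    dipping to ``-acc2`` over t2, with ``acc2 = acc1 * t1 / t2`` so the two
    areas cancel.  The sampled negative lobe is rescaled (an O(h^2)
    adjustment) so the trapezoidal integral of the returned series is
    exactly zero, preserving the zero-net-velocity constraint on the
    discrete grid.
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("both stage durations must be positive")
    acc2 = acc1 * t1 / t2
    n = int(round((t1 + t2) * fs)) + 1
    t = np.arange(n) / fs
    acc = np.zeros(n)

    m = t < t1 / 2
    acc[m] = acc1 * t[m] / (t1 / 2)
    m = (t >= t1 / 2) & (t < t1)
    acc[m] = acc1 * (t1 - t[m]) / (t1 / 2)
    m = (t >= t1) & (t < t1 + t2 / 2)
    acc[m] = -acc2 * (t[m] - t1) / (t2 / 2)
    m = t >= t1 + t2 / 2
    acc[m] = -acc2 * np.clip(t1 + t2 - t[m], 0.0, None) / (t2 / 2)

    pos = np.clip(acc, 0.0, None)
    neg = np.clip(acc, None, 0.0)
    area_pos = np.trapezoid(pos, t)
    area_neg = -np.trapezoid(neg, t)
    if area_neg > 0:
        acc = pos + neg * (area_pos / area_neg)
    return acc


def reconstruct_kinematics(
    trial: PreprocessedTrial,
    acc1: float = DEFAULT_ACC1,
) -> ReconstructionResult:
    """Reconstruct the intended motion for one trial's stretch window.

    The reconstructed acceleration is integrated twice (trapezoidal) to an
    angle curve, which is scaled so its range matches the actual range of
    motion (trapezoidal integral of the measured speed); the same scale is
    applied through the whole chain so the reconstructed angle, speed and
    acceleration stay mutually consistent and the acceleration keeps its
    exact zero net integral.
    """
    if trial.move_on is None or trial.move_off is None:
        raise ValueError("trial has no movement bounds")
    fs = trial.fs_gyro
    tmax_index, t1, t2 = split_phases(trial.speed, trial.move_on, trial.move_off, fs)
    if t1 <= 0 or t2 <= 0:
        raise ValueError("degenerate stretch: speed maximum at a window edge")

    window = trial.speed[trial.move_on : trial.move_off + 1]
    acc = reconstruct_acceleration(t1, t2, acc1, fs)
    # match the window's sample count (rounding of t1+t2 can differ by one)
    if len(acc) != len(window):
        acc = np.interp(
            np.linspace(0.0, 1.0, len(window)), np.linspace(0.0, 1.0, len(acc)), acc
        )

    dx = 1.0 / fs
    vel = cumulative_trapezoid(acc, dx=dx, initial=0.0)
    ang = cumulative_trapezoid(vel, dx=dx, initial=0.0)
    actual_angle = cumulative_trapezoid(window, dx=dx, initial=0.0)
    actual_rom = float(actual_angle.max() - actual_angle.min())
    unscaled_rom = float(ang.max() - ang.min())
    if unscaled_rom == 0:
        raise ValueError("zero reconstructed range of motion")

    # scaling commutes with the integrations, so the scaled triplet
    # (acc, vel, ang) stays exactly consistent under the trapezoid rule and
    # keeps the zero-net-velocity constraint of the acceleration series;
    # differentiating the scaled angle back down would reproduce the same
    # curves to O(h^2) while breaking those exact identities at the edges
    scale = actual_rom / unscaled_rom
    recon_angle = ang * scale
    recon_speed = vel * scale
    recon_acc = acc * scale
    return ReconstructionResult(
        t1=t1,
        t2=t2,
        tmax_index=tmax_index,
        acc1=acc1,
        acc2=acc1 * t1 / t2,
        recon_angle=recon_angle,
        recon_speed=recon_speed,
        recon_acc=recon_acc,
        scale_factor=scale,
    )


def median_frequency(x: np.ndarray, fs: float = 100.0) -> float:
    """Median frequency of a series via the raw periodogram (Hz).

    The series is mean-detrended; the one-sided periodogram excludes the DC
    bin; the frequency at which the cumulative power first reaches half the
    total is found with linear interpolation between bins.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 32:
        raise ValueError("series too short for a spectral estimate (need >= 32 samples)")
    f, p = periodogram(x, fs=fs, detrend="constant", window="boxcar")
    f, p = f[1:], p[1:]  # exclude DC
    total = p.sum()
    if total <= 0:
        raise ValueError("zero-variance series has no median frequency")
    c = np.cumsum(p)
    half = total / 2.0
    i = int(np.searchsorted(c, half))
    f_lo = f[i - 1] if i > 0 else 0.0
    c_lo = c[i - 1] if i > 0 else 0.0
    if c[i] == c_lo:
        return float(f[i])
    return float(f_lo + (half - c_lo) / (c[i] - c_lo) * (f[i] - f_lo))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance curve has no correlation")
    return float(np.corrcoef(a, b)[0, 1])


def extract_kinematic_biomarkers(
    session: Sequence[PreprocessedTrial],
    duration_range: tuple[float, float] = (1.0, 2.0),
    acc1: float = DEFAULT_ACC1,
) -> KinematicBiomarkers:
    """Per-subject biomarkers from the eligible trials of a session.

    Eligible trials are QC-passed with a stretch duration inside
    ``duration_range`` (default 1-2 s).  For each, the actual angle (single
    trapezoidal integral of speed, origin 0) and acceleration (central
    differences of speed) are compared with the constant-jerk
    reconstruction via Pearson correlation, and the median frequency of the
    actual acceleration is taken; the subject's biomarkers are the
    arithmetic means across eligible trials.
    """
    lo, hi = duration_range
    rows = []
    for t in session:
        if not (t.qc_pass and lo <= t.stretch_duration <= hi):
            continue
        try:
            recon = reconstruct_kinematics(t, acc1=acc1)
        except ValueError as exc:
            logger.info("trial %s skipped for biomarkers: %s", t.trial_id, exc)
            continue
        dx = 1.0 / t.fs_gyro
        window = t.speed[t.move_on : t.move_off + 1]
        actual_angle = cumulative_trapezoid(window, dx=dx, initial=0.0)
        actual_acc = np.gradient(window, dx)
        rows.append(
            (
                _pearson(actual_angle, recon.recon_angle),
                _pearson(window, recon.recon_speed),
                _pearson(actual_acc, recon.recon_acc),
                median_frequency(actual_acc, t.fs_gyro),
            )
        )
    if not rows:
        raise ValueError("no_eligible_trials: no QC-passed trial in the duration window")
    arr = np.array(rows)
    return KinematicBiomarkers(
        corr_angle=float(arr[:, 0].mean()),
        corr_speed=float(arr[:, 1].mean()),
        corr_acc=float(arr[:, 2].mean()),
        mdf_acc=float(arr[:, 3].mean()),
        n_trials_used=len(rows),
    )
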