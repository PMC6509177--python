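"""Lambda model: tonic stretch reflex threshold from DSRT-velocity regression.

For each trial the dynamic stretch reflex threshold (DSRT) is the angle
traversed from movement onset to the moment the EMG burst is evoked,
obtained by integrating the angular speed.  Across a session the DSRT
decreases with mean stretch velocity; an ordinary least-squares line through
(mean velocity, DSRT) pairs — with a one-shot 95% prediction-interval
outlier exclusion and a single refit — extrapolates to zero velocity.  Its
intercept is the tonic stretch reflex threshold (TSRT), the lambda model's
spasticity biomarker.  Subjects whose trials mostly lack an evoked response
(healthy reflex regulation) are assigned the fallback TSRT of 120 degrees,
the guaranteed range of motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .preprocess import PreprocessedTrial

logger = logging.getLogger(__name__)

__all__ = [
    "DsrtPoint",
    "LambdaModel",
    "LambdaResults",
    "compute_dsrt",
    "fit_lambda",
    "extract_tsrt",
    "FALLBACK_TSRT",
]

#: TSRT assigned when a session lacks evoked EMG in most trials (degrees).
FALLBACK_TSRT = 120.0


@dataclass(frozen=True)
class DsrtPoint:
    """One (mean stretch velocity, DSRT) observation from a single trial."""

    mean_speed: float
    dsrt: float
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.mean_speed <= 0:
            raise ValueError("mean_speed must be positive")
        if not 0.0 <= self.dsrt <= 140.0:
            raise ValueError("dsrt must lie in [0, 140] degrees")


@dataclass
class LambdaResults:
    """Fitted lambda model for one subject.

    ``intercept_tsrt`` is the TSRT biomarker (degrees); ``slope`` is in
    degrees per (deg/s).  ``outlier_mask`` flags the points excluded by the
    95% prediction-interval rule; ``r2`` is recomputed on the retained
    points.  When ``fallback_used`` the subject lacked evoked EMG in most
    trials and TSRT is the 120-degree fallback (slope and r2 are NaN).
    """

    slope: float
    intercept_tsrt: float
    r2: float
    n_points: int
    outlier_mask: np.ndarray
    fallback_used: bool = False
    points: tuple[DsrtPoint, ...] = ()

    @property
    def tsrt(self) -> float:
        return self.intercept_tsrt

    def predict(self, mean_speed: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(mean_speed) + self.intercept_tsrt

    def summary(self) -> str:
        lines = [
            "Lambda model (DSRT ~ mean stretch velocity)",
            "=" * 46,
            f"{'TSRT (intercept)':<28}{self.intercept_tsrt:>12.3f} deg",
            f"{'slope':<28}{self.slope:>12.4f} deg/(deg/s)",
            f"{'R^2 (retained points)':<28}{self.r2:>12.4f}",
            f"{'points (with onset)':<28}{self.n_points:>12d}",
            f"{'outliers excluded':<28}{int(np.sum(self.outlier_mask)):>12d}",
            f"{'fallback (120 deg) used':<28}{str(self.fallback_used):>12}",
        ]
        return "\n".join(lines)

    def to_record(self, subject_id: str = "") -> dict:
        return {
            "subject_id": subject_id,
            "tsrt": float(self.intercept_tsrt),
            "slope": None if np.isnan(self.slope) else float(self.slope),
            "r2": None if np.isnan(self.r2) else float(self.r2),
            "n_points": int(self.n_points),
            "fallback_used": bool(self.fallback_used),
        }


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple OLS: returns (slope, intercept)."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("ill-conditioned: zero variance in stretch velocity")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return float(slope), float(ym - slope * xm)


def _r2(x: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> float:
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0
    ss_res = np.sum((y - slope * x - intercept) ** 2)
    return float(1.0 - ss_res / ss_tot)


class LambdaModel:
    """DSRT-versus-velocity regression model for one subject's session.

    Parameters
    ----------
    points : sequence of DsrtPoint
        Per-trial (mean velocity, DSRT) observations; at least 2, and at
        least 3 for the outlier-exclusion pass to engage.

    ``fit()`` performs the initial OLS fit, flags points outside the 95%
    prediction interval for individual observations, and refits once on the
    retained points (no iteration, so exclusion cannot cascade).
    """

    def __init__(self, points: Sequence[DsrtPoint]):
        if len(points) < 2:
            raise ValueError("need at least 2 DSRT points to fit a line")
        self.points = tuple(points)
        self.x = np.array([p.mean_speed for p in points], dtype=float)
        self.y = np.array([p.dsrt for p in points], dtype=float)

    @classmethod
    def from_session(cls, session: Sequence[PreprocessedTrial]) -> "LambdaModel":
        pts = []
        for t in session:
            if not t.qc_pass:
                continue
            d = compute_dsrt(t)
            if d is not None:
                pts.append(DsrtPoint(mean_speed=t.mean_speed, dsrt=d, trial_id=t.trial_id))
        return cls(pts)

    def fit(self, confidence: float = 0.95) -> LambdaResults:
        x, y = self.x, self.y
        n = len(x)
        slope0, inter0 = _ols(x, y)
        mask = np.zeros(n, dtype=bool)

        if n >= 3:
            resid = y - (slope0 * x + inter0)
            dof = n - 2
            s2 = np.sum(resid**2) / dof
            if s2 > 0:
                tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
                sxx = np.sum((x - x.mean()) ** 2)
                half_width = tcrit * np.sqrt(s2) * np.sqrt(1.0 + 1.0 / n + (x - x.mean()) ** 2 / sxx)
                mask = np.abs(resid) > half_width

        keep = ~mask
        if keep.sum() >= 2 and mask.any():
            slope, inter = _ols(x[keep], y[keep])
        else:
            slope, inter = slope0, inter0
            mask = np.zeros(n, dtype=bool)
            keep = ~mask
        r2 = _r2(x[keep], y[keep], slope, inter)
        return LambdaResults(
            slope=slope,
            intercept_tsrt=inter,
            r2=r2,
            n_points=n,
            outlier_mask=mask,
            fallback_used=False,
            points=self.points,
        )


def fit_lambda(points: Sequence[DsrtPoint], confidence: float = 0.95) -> LambdaResults:
    """Functional wrapper: ``LambdaModel(points).fit(confidence)``."""
    return LambdaModel(points).fit(confidence)


def compute_dsrt(trial: PreprocessedTrial) -> Optional[float]:
    """Angle traversed from movement onset to EMG onset (degrees).

    Trapezoidal integral of the angular speed from ``move_on`` to the EMG
    onset mapped onto the 100 Hz time base (nearest sample).  ``None`` when
    the trial has no EMG onset, or when the detections are inconsistent
    (onset before movement start).
    """
    if trial.emg_onset is None or trial.move_on is None:
        return None
    j = int(round(trial.emg_onset / trial.fs_emg * trial.fs_gyro))
    j = min(j, len(trial.speed) - 1)
    if j < trial.move_on:
        logger.warning(
            "trial %s: EMG onset precedes movement onset; DSRT undefined", trial.trial_id
        )
        return None
    if j == trial.move_on:
        return 0.0
    seg = trial.speed[trial.move_on : j + 1]
    return float(np.trapezoid(seg, dx=1.0 / trial.fs_gyro))


def extract_tsrt(
    session: Sequence[PreprocessedTrial],
    majority_threshold: float = 0.5,
    min_points: int = 3,
    confidence: float = 0.95,
) -> LambdaResults:
    """Per-subject TSRT with the healthy-fallback rule.

    The regression runs only when the fraction of QC-passed trials with a
    detected EMG onset is *strictly greater* than ``majority_threshold``
    (and at least ``min_points`` DSRT points exist); otherwise the subject
    is treated as lacking a typical evoked response and TSRT is set to the
    120-degree fallback.
    """
    passed = [t for t in session if t.qc_pass]
    if not passed:
        raise ValueError("empty session: no QC-passed trials")

    pts = []
    for t in passed:
        d = compute_dsrt(t)
        if d is not None:
            pts.append(DsrtPoint(mean_speed=t.mean_speed, dsrt=min(d, 140.0), trial_id=t.trial_id))

    frac = len(pts) / len(passed)
    if frac <= majority_threshold or len(pts) < min_points:
        return LambdaResults(
            slope=np.nan,
            intercept_tsrt=FALLBACK_TSRT,
            r2=np.nan,
            n_points=len(pts),
            outlier_mask=np.zeros(len(pts), dtype=bool),
            fallback_used=True,
            points=tuple(pts),
        )
    return LambdaModel(pts).fit(confidence)
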