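"""Utility trajectories and area-under-the-curve QALYs over a 1-year horizon.

The trial design measures utility at baseline and at a 3-month follow-up and
assumes the follow-up utility holds for the remainder of the year.  QALYs are
the trapezoidal area under the resulting piecewise-linear utility curve; the
QALY *gain* is measured against the baseline utility held constant over the
horizon (the area between the curve and the baseline-level line), which is
what makes year-scale gains of order 0.01 arise from a 3-month change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

DAYS_PER_YEAR = 365.25

DEFAULT_FOLLOWUP_YEARS = 0.25
DEFAULT_HORIZON_YEARS = 1.0


@dataclass(frozen=True)
class UtilityTrajectory:
    """Assessment times (years, ascending from 0) and matching utility weights.

    Between points the utility changes linearly; beyond the last point it is
    held constant up to ``horizon``.
    """

    times: tuple[float, ...]
    utilities: tuple[float, ...]
    horizon: float = DEFAULT_HORIZON_YEARS

    def __post_init__(self) -> None:
        if len(self.times) != len(self.utilities):
            raise ValidationError("times and utilities must have equal length")
        if len(self.times) == 0:
            raise ValidationError("trajectory needs at least one point")
        if self.horizon <= 0:
            raise ValidationError(f"horizon must be > 0, got {self.horizon}")
        if self.times[0] != 0.0:
            raise ValidationError(f"first assessment time must be 0, got {self.times[0]}")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("times must be strictly increasing")
        if self.times[-1] > self.horizon:
            raise ValidationError(
                f"last time {self.times[-1]} exceeds horizon {self.horizon}"
            )
        for u in self.utilities:
            if not 0.0 <= u <= 1.0:
                raise ValidationError(f"utility {u} outside [0, 1]")


@dataclass(frozen=True)
class QalyResult:
    """QALYs over the horizon, the gain vs. baseline-held-constant, and the gain in days."""

    qaly_total: float
    qaly_gain: float
    days_equivalent: float


def build_trajectory(
    u_baseline: float,
    u_followup: float,
    t_followup: float = DEFAULT_FOLLOWUP_YEARS,
    horizon: float = DEFAULT_HORIZON_YEARS,
) -> UtilityTrajectory:
    """Two-assessment trajectory: linear to follow-up, constant thereafter."""
    if not (0.0 < t_followup <= horizon):
        raise ValidationError(
            f"t_followup must lie in (0, horizon={horizon}], got {t_followup}"
        )
    points = [(0.0, u_baseline), (t_followup, u_followup)]
    if t_followup < horizon:
        points.append((horizon, u_followup))
    times, utils = zip(*points)
    return UtilityTrajectory(times=times, utilities=utils, horizon=horizon)


def qaly_auc(traj: UtilityTrajectory) -> QalyResult:
    """Trapezoidal QALYs over [0, horizon], with constant extrapolation past the last point."""
    times = np.asarray(traj.times, dtype=float)
    utils = np.asarray(traj.utilities, dtype=float)
    if times[-1] < traj.horizon:
        times = np.append(times, traj.horizon)
        utils = np.append(utils, utils[-1])
    if np.all(utils == utils[0]):
        # flat curve: avoid float cancellation so the gain is exactly zero
        total = float(utils[0] * traj.horizon)
    else:
        total = float(np.trapezoid(utils, times))
    gain = total - traj.utilities[0] * traj.horizon
    return QalyResult(
        qaly_total=total,
        qaly_gain=gain,
        days_equivalent=gain * DAYS_PER_YEAR,
    )


def implied_utility_change(
    qaly_gain: float,
    t_followup: float = DEFAULT_FOLLOWUP_YEARS,
    horizon: float = DEFAULT_HORIZON_YEARS,
) -> float:
    """Follow-up utility change that produces ``qaly_gain`` under the default shape.

    Inverse of :func:`qaly_auc` composed with :func:`build_trajectory`:
    the gain of the two-assessment trajectory equals
    ``delta_u * (horizon - t_followup / 2)``.
    """
    if not (0.0 < t_followup <= horizon):
        raise ValidationError(
            f"t_followup must lie in (0, horizon={horizon}], got {t_followup}"
        )
    denom = horizon - t_followup / 2.0
    if denom == 0.0:
        raise ValidationError("degenerate geometry: horizon - t_followup/2 is zero")
    return qaly_gain / denom
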