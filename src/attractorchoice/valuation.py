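"""Options, trials, subjective values and the manipulation-point algebra.

A trial of the foraging task offers two coins: one small-and-near (SN) and
one large-and-far (LF).  Three derived quantities describe a trial in
relational terms:

* the *reward ratio* ``r = sn.reward / lf.reward`` (in (0, 1] because the SN
  reward is the smaller one),
* the *interval* ``I = lf.distance - sn.distance`` in grid fields,
* the *manipulation point* ``m = r - p*(I)``, the signed distance of the
  trial's reward ratio from the participant's indifference point at that
  interval.  ``m < 0`` means the LF option is subjectively superior,
  ``m > 0`` means the SN option is.

Subjective value follows hyperbolic discounting over distance,
``omega = reward / (1 + k * distance)`` with individual discount rate ``k``,
in analogy to hyperbolic delay discounting.  For that form the indifference
ratio at interval ``I`` with SN distance ``d`` has the closed form
``p*(I) = (1 + k d) / (1 + k (d + I))``, which is strictly decreasing in
``I`` for ``k > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np

__all__ = [
    "REWARD_RANGE",
    "DISTANCE_RANGE",
    "Option",
    "Trial",
    "ParticipantProfile",
    "reward_ratio",
    "interval",
    "subjective_value",
    "analytic_indifference_point",
    "reference_indifference_point",
    "manipulation_point",
    "control_parameter",
]

#: Inclusive credit range of coin rewards.
REWARD_RANGE = (1, 99)
#: Inclusive field range of coin distances.
DISTANCE_RANGE = (2, 15)


@dataclass(frozen=True)
class Option:
    """One choice alternative: a coin with a printed reward at some distance.

    Parameters
    ----------
    reward
        Integer credit value in ``[1, 99]``.
    distance
        Integer distance from the avatar in grid fields, in ``[2, 15]``.
    """

    reward: int
    distance: int

    def __post_init__(self) -> None:
        lo, hi = REWARD_RANGE
        if not (lo <= self.reward <= hi):
            raise ValueError(f"reward {self.reward} outside [{lo}, {hi}]")
        lo, hi = DISTANCE_RANGE
        if not (lo <= self.distance <= hi):
            raise ValueError(f"distance {self.distance} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class Trial:
    """A single binary choice between an SN and an LF option.

    The SN option is strictly smaller in reward and strictly nearer in
    distance; degenerate trials are rejected at construction.
    """

    sn: Option
    lf: Option

    def __post_init__(self) -> None:
        if self.sn.reward >= self.lf.reward:
            raise ValueError(
                f"SN reward {self.sn.reward} must be < LF reward {self.lf.reward}"
            )
        if self.sn.distance >= self.lf.distance:
            raise ValueError(
                f"SN distance {self.sn.distance} must be < LF distance {self.lf.distance}"
            )


def reward_ratio(trial: Trial) -> float:
    """SN reward divided by LF reward, in (0, 1)."""
    return trial.sn.reward / trial.lf.reward


def interval(trial: Trial) -> int:
    """LF distance minus SN distance, in grid fields (>= 1)."""
    return trial.lf.distance - trial.sn.distance


def subjective_value(option: Option, discount_rate: float) -> float:
    """Hyperbolically distance-discounted value ``reward / (1 + k * distance)``.

    Strictly increasing in reward and, for ``discount_rate > 0``, strictly
    decreasing in distance.
    """
    if discount_rate < 0:
        raise ValueError(f"discount_rate must be >= 0, got {discount_rate}")
    return option.reward / (1.0 + discount_rate * option.distance)


def analytic_indifference_point(
    discount_rate: float, interval: float, sn_distance: float = 2.0
) -> float:
    """Closed-form indifference ratio ``(1 + k d) / (1 + k (d + I))``.

    At this reward ratio the discounted values of the two options are exactly
    equal (before integer rounding of rewards).
    """
    if discount_rate < 0:
        raise ValueError(f"discount_rate must be >= 0, got {discount_rate}")
    k = discount_rate
    return (1.0 + k * sn_distance) / (1.0 + k * (sn_distance + interval))


def reference_indifference_point(discount_rate: float, interval: float) -> float:
    """Analytic p*(I) pooled over the two SN distances used in the design.

    The task crosses SN distances 2 and 3 with every interval; a logistic fit
    of choice against reward ratio pools both, so the recoverable indifference
    point lies between the two analytic values.  Their mean is the reference.
    """
    return 0.5 * (
        analytic_indifference_point(discount_rate, interval, sn_distance=2.0)
        + analytic_indifference_point(discount_rate, interval, sn_distance=3.0)
    )


@dataclass
class ParticipantProfile:
    """Per-interval indifference points describing one participant.

    ``indifference_points`` maps interval (fields) to the reward ratio at
    which the participant is indifferent.  For synthetic participants the
    generating ``discount_rate`` is carried along for recovery scoring.
    Intervals whose psychometric fit failed are absent from the map; the
    profile is ``flagged`` when it cannot support design generation.
    """

    indifference_points: Dict[int, float]
    discount_rate: Optional[float] = None
    flagged: bool = False
    flag_reason: str = ""
    fit_info: Dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, p in self.indifference_points.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"indifference point at interval {i} is {p}, not in (0, 1)")

    @property
    def fitted_intervals(self) -> list:
        return sorted(self.indifference_points)

    def p_star(self, at_interval: float) -> float:
        """Indifference point at ``at_interval``, linearly interpolated.

        Piecewise-linear between fitted intervals, constant beyond the
        endpoints.  Requires at least two fitted intervals.
        """
        knots = self.fitted_intervals
        if len(knots) < 2:
            raise ValueError(
                f"need >= 2 fitted indifference points to interpolate, have {len(knots)}"
            )
        xs = np.asarray(knots, dtype=float)
        ys = np.asarray([self.indifference_points[i] for i in knots], dtype=float)
        return float(np.interp(at_interval, xs, ys))

    @classmethod
    def from_discount_rate(
        cls, discount_rate: float, intervals=(1, 4, 8, 12)
    ) -> "ParticipantProfile":
        """Ground-truth profile of a synthetic participant (no fitting)."""
        points = {
            int(i): reference_indifference_point(discount_rate, i) for i in intervals
        }
        return cls(indifference_points=points, discount_rate=discount_rate)


def manipulation_point(trial: Trial, profile: ParticipantProfile) -> float:
    """Signed offset ``m = r - p*(I)`` of a trial from indifference.

    Negative ``m`` denotes a superior subjective value of the LF option,
    positive ``m`` a superior SN option.
    """
    return reward_ratio(trial) - profile.p_star(interval(trial))


def control_parameter(m: float, gain: float = 1.0) -> float:
    """Map a manipulation point onto the attractor model's control parameter.

    Linear with configurable gain: ``c = gain * m``, so ``c = 0`` exactly at
    indifference and the map is antisymmetric in ``m``.
    """
    if gain <= 0:
        raise ValueError(f"gain must be > 0, got {gain}")
    return gain * m
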