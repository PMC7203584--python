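"""Assessment block, indifference-point estimation and sequential designs.

The assessment block factorially crosses 8 reward ratios, 2 SN distances
and 4 intervals (64 trials per set, 5 sets).  From its choices a logistic
psychometric function of reward ratio is fitted per interval; the inflection
point ``p* = -a/b`` is the indifference point.  The three experimental
blocks then step a participant-specific manipulation point through a fixed
12-value schedule spanning [-0.3, +0.3], realised by varying LF distance
(distance block), SN reward (value block), or both (combined block).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence as Seq

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .valuation import (
    DISTANCE_RANGE,
    Option,
    ParticipantProfile,
    Trial,
    interval as trial_interval,
    reward_ratio as trial_reward_ratio,
)

__all__ = [
    "RATIO_LEVELS",
    "SN_DISTANCE_LEVELS",
    "INTERVAL_LEVELS",
    "LF_REWARD_RANGE",
    "SN_TO_LF",
    "LF_TO_SN",
    "BLOCK_KINDS",
    "DesignInfeasibleError",
    "Sequence",
    "BlockDesign",
    "AssessmentDesign",
    "manipulation_schedule",
    "generate_assessment_set",
    "generate_assessment_block",
    "fit_logistic_psychometric",
    "fit_indifference_points",
    "indifference_curve",
    "valid_intervals",
    "generate_value_sequence",
    "generate_distance_sequence",
    "generate_combined_sequence",
    "generate_block",
]

#: Reward-ratio levels of the assessment factorial (20–99 %).
RATIO_LEVELS = (0.20, 0.50, 0.70, 0.80, 0.88, 0.93, 0.97, 0.99)
#: SN-distance levels (fields).
SN_DISTANCE_LEVELS = (2, 3)
#: Interval levels (fields).
INTERVAL_LEVELS = (1, 4, 8, 12)
#: Discrete uniform range of LF rewards (credits, inclusive).
LF_REWARD_RANGE = (55, 99)
#: Integer interval grid available to the sequential designs.
SEQUENCE_INTERVAL_GRID = tuple(range(1, 13))

SN_TO_LF = "SN_to_LF"  # manipulation points descend +0.3 -> -0.3
LF_TO_SN = "LF_to_SN"  # manipulation points ascend  -0.3 -> +0.3
BLOCK_KINDS = ("distance", "reward", "combined")

N_SCHEDULE_STEPS = 12
SEQUENCES_PER_DIRECTION = 8


class DesignInfeasibleError(RuntimeError):
    """A profile cannot support the requested sequential manipulation."""


def manipulation_schedule() -> np.ndarray:
    """The 12 equally spaced manipulation points spanning [-0.3, +0.3]."""
    return np.linspace(-0.3, 0.3, N_SCHEDULE_STEPS)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _directed_schedule(direction: str) -> np.ndarray:
    sched = manipulation_schedule()
    if direction == LF_TO_SN:
        return sched
    if direction == SN_TO_LF:
        return sched[::-1].copy()
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# assessment block
# ---------------------------------------------------------------------------

@dataclass
class AssessmentDesign:
    """Factorial assessment block: ``n_sets`` shuffled 64-trial sets."""

    sets: List[List[Trial]]

    @property
    def trials(self) -> List[Trial]:
        return [t for s in self.sets for t in s]

    def to_frame(self) -> pd.DataFrame:
        return _trials_to_frame(self.trials, block="assessment")


def generate_assessment_set(rng: np.random.Generator) -> List[Trial]:
    """One complete 8 x 2 x 4 factorial set of 64 trials, shuffled.

    LF rewards are drawn per trial from the discrete uniform distribution on
    [55, 99]; SN rewards are the ratio times the LF reward, rounded to the
    nearest credit.
    """
    trials = []
    for ratio in RATIO_LEVELS:
        for d_sn in SN_DISTANCE_LEVELS:
            for ivl in INTERVAL_LEVELS:
                lf_reward = int(rng.integers(LF_REWARD_RANGE[0], LF_REWARD_RANGE[1] + 1))
                sn_reward = min(max(_round_half_up(ratio * lf_reward), 1), lf_reward - 1)
                trials.append(
                    Trial(
                        sn=Option(reward=sn_reward, distance=d_sn),
                        lf=Option(reward=lf_reward, distance=d_sn + ivl),
                    )
                )
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def generate_assessment_block(
    rng: np.random.Generator, n_sets: int = 5
) -> AssessmentDesign:
    return AssessmentDesign(sets=[generate_assessment_set(rng) for _ in range(n_sets)])


# ---------------------------------------------------------------------------
# indifference-point estimation
# ---------------------------------------------------------------------------

def fit_logistic_psychometric(
    ratios: np.ndarray, chose_sn: np.ndarray, ridge: float = 1e-4
) -> dict:
    """Fit ``P(SN) = expit(a + b r)`` by (lightly penalized) max likelihood.

    The ridge term keeps the optimum finite under perfect separation, where
    the unpenalized ML slope diverges; for non-degenerate data its effect is
    negligible.  Returns ``a``, ``b``, the inflection ``p_star = -a/b`` and
    diagnostics.
    """
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(chose_sn, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("ratios and choices must be equal-length, nonempty")

    def nll(theta):
        a, b = theta
        z = a + b * x
        # log(1+exp) in a numerically stable form
        val = np.sum(np.logaddexp(0.0, z)) - np.sum(y * z)
        return val + ridge * (a * a + b * b)

    def grad(theta):
        a, b = theta
        p = expit(a + b * x)
        r = p - y
        return np.array([np.sum(r) + 2 * ridge * a, np.sum(r * x) + 2 * ridge * b])

    res = minimize(nll, x0=np.array([0.0, 1.0]), jac=grad, method="BFGS")
    a, b = res.x
    separated = bool(x[y == 1].size and x[y == 0].size and x[y == 1].min() > x[y == 0].max())
    return {
        "a": float(a),
        "b": float(b),
        "p_star": float(-a / b) if b != 0 else math.nan,
        "converged": bool(res.success or res.fun < nll(np.array([0.0, 1.0]))),
        "separated": separated,
        "n": int(x.size),
    }


def fit_indifference_points(
    choices: pd.DataFrame,
    intervals: Iterable[int] = INTERVAL_LEVELS,
    p_star_bounds: tuple = (0.01, 0.99),
) -> ParticipantProfile:
    """Estimate per-interval indifference points from assessment choices.

    ``choices`` needs columns ``interval``, ``reward_ratio`` and ``choice``
    (``SN``/``LF``; timeouts are dropped).  Per interval a logistic of
    choice against reward ratio is fitted; its inflection, clamped to
    ``p_star_bounds``, is the indifference point.  Intervals with
    one-option-only data or a non-increasing psychometric slope yield no
    estimate; the profile is flagged when fewer than two intervals could be
    fitted, the situation in which a participant's choices cannot support
    a sufficient sequential manipulation.
    """
    valid = choices[choices["choice"].isin(["SN", "LF"])]
    points: Dict[int, float] = {}
    info: Dict[int, dict] = {}
    for ivl in intervals:
        sub = valid[valid["interval"] == ivl]
        ratios = sub["reward_ratio"].to_numpy(dtype=float)
        y = (sub["choice"] == "SN").to_numpy(dtype=float)
        if ratios.size == 0 or np.unique(ratios).size < 2:
            info[ivl] = {"skipped": "insufficient ratio levels", "n": int(ratios.size)}
            continue
        if y.min() == y.max():
            info[ivl] = {"skipped": "all one option", "n": int(ratios.size)}
            continue
        fit = fit_logistic_psychometric(ratios, y)
        info[ivl] = fit
        if not math.isfinite(fit["p_star"]) or fit["b"] <= 0:
            info[ivl]["skipped"] = "non-increasing psychometric"
            continue
        points[int(ivl)] = float(np.clip(fit["p_star"], *p_star_bounds))
    flagged = len(points) < 2
    reason = "" if not flagged else f"only {len(points)} interval(s) fitted"
    return ParticipantProfile(
        indifference_points=points, flagged=flagged, flag_reason=reason, fit_info=info
    )


def indifference_curve(profile: ParticipantProfile) -> Callable[[float], float]:
    """Piecewise-linear indifference-point curve over intervals.

    Passes exactly through the fitted knots and extrapolates as a constant
    beyond the endpoint intervals.  Requires at least two fitted intervals.
    """
    if len(profile.fitted_intervals) < 2:
        raise ValueError("indifference curve needs >= 2 fitted intervals")
    return profile.p_star


# ---------------------------------------------------------------------------
# sequential-manipulation blocks
# ---------------------------------------------------------------------------

@dataclass
class Sequence:
    """A 12-trial run stepping the manipulation point monotonically.

    ``target_m`` is the schedule the design aims at; ``target_ratio`` the
    corresponding real-valued reward ratios before integer rounding (for
    the distance block, where the ratio is fixed, ``target_m`` holds the
    post-hoc manipulation points implied by the fitted indifference curve).
    """

    block_kind: str
    direction: str
    trials: List[Trial]
    target_m: np.ndarray
    target_ratio: np.ndarray

    def __post_init__(self) -> None:
        if len(self.trials) != N_SCHEDULE_STEPS:
            raise ValueError(f"a sequence has {N_SCHEDULE_STEPS} trials, got {len(self.trials)}")


@dataclass
class BlockDesign:
    """One experimental block: 8 sequences per direction, 192 trials."""

    block_kind: str
    sequences: List[Sequence]

    @property
    def n_trials(self) -> int:
        return sum(len(s.trials) for s in self.sequences)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for sid, seq in enumerate(self.sequences):
            f = _trials_to_frame(seq.trials, block=self.block_kind)
            f["sequence_id"] = sid
            f["trial_idx"] = np.arange(len(seq.trials))
            f["direction"] = seq.direction
            f["manipulation_point"] = seq.target_m
            f["design_ratio"] = seq.target_ratio
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def _trials_to_frame(trials: List[Trial], block: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block": block,
            "sequence_id": -1,
            "trial_idx": np.arange(len(trials)),
            "direction": "",
            "sn_reward": [t.sn.reward for t in trials],
            "sn_distance": [t.sn.distance for t in trials],
            "lf_reward": [t.lf.reward for t in trials],
            "lf_distance": [t.lf.distance for t in trials],
            "reward_ratio": [trial_reward_ratio(t) for t in trials],
            "interval": [trial_interval(t) for t in trials],
            "manipulation_point": np.nan,
            "design_ratio": np.nan,
        }
    )


def valid_intervals(
    profile: ParticipantProfile,
    m: float,
    grid: Seq[int] = SEQUENCE_INTERVAL_GRID,
    max_sn_distance: int = max(SN_DISTANCE_LEVELS),
) -> List[int]:
    """Intervals at which ``p*(I) + m`` is a valid reward ratio (0 < x < 1).

    Also requires the implied LF distance to stay within the board range.
    Raises :class:`DesignInfeasibleError` naming ``m`` if no interval
    qualifies.
    """
    curve = indifference_curve(profile)
    good = [
        int(i)
        for i in grid
        if 0.0 < curve(i) + m < 1.0 and max_sn_distance + i <= DISTANCE_RANGE[1]
    ]
    if not good:
        raise DesignInfeasibleError(
            f"no interval admits manipulation point m={m:+.4f} for this profile"
        )
    return good


def _draw_sequence_constants(rng: np.random.Generator) -> tuple:
    d_sn = int(rng.integers(SN_DISTANCE_LEVELS[0], SN_DISTANCE_LEVELS[-1] + 1))
    lf_reward = int(rng.integers(LF_REWARD_RANGE[0], LF_REWARD_RANGE[1] + 1))
    return d_sn, lf_reward


def _sn_reward_from_ratio(ratio: float, lf_reward: int) -> int:
    return min(max(_round_half_up(ratio * lf_reward), 1), lf_reward - 1)


def generate_value_sequence(
    profile: ParticipantProfile, direction: str, rng: np.random.Generator
) -> Sequence:
    """Value (reward) block sequence: only the SN reward changes.

    One interval, valid for every point of the schedule simultaneously, is
    drawn and held fixed; per trial the SN reward realises the scheduled
    ratio ``p*(I) + m_t``.
    """
    sched = _directed_schedule(direction)
    curve = indifference_curve(profile)
    feasible = [
        i
        for i in SEQUENCE_INTERVAL_GRID
        if all(0.0 < curve(i) + m < 1.0 for m in sched)
        and max(SN_DISTANCE_LEVELS) + i <= DISTANCE_RANGE[1]
    ]
    if not feasible:
        raise DesignInfeasibleError(
            "no interval is valid for the full schedule (need 0.3 < p*(I) < 0.7)"
        )
    d_sn, lf_reward = _draw_sequence_constants(rng)
    ivl = int(rng.choice(feasible))
    p = curve(ivl)
    ratios = p + sched
    trials = [
        Trial(
            sn=Option(reward=_sn_reward_from_ratio(r, lf_reward), distance=d_sn),
            lf=Option(reward=lf_reward, distance=d_sn + ivl),
        )
        for r in ratios
    ]
    return Sequence("reward", direction, trials, target_m=sched.copy(), target_ratio=ratios)


def generate_distance_sequence(
    profile: ParticipantProfile, direction: str, rng: np.random.Generator
) -> Sequence:
    """Distance block sequence: only the LF distance changes.

    The reward ratio is drawn once, uniformly between the indifference
    points at the medium intervals 6 and 7; the interval then steps through
    the twelve consecutive values 1..12, ascending when the manipulation
    runs LF-to-SN (increasing distance makes LF worse) and descending
    otherwise.  The recorded manipulation points are post hoc:
    ``m_t = r - p*(I_t)`` under the fitted indifference curve.
    """
    curve = indifference_curve(profile)
    lo, hi = sorted((curve(7.0), curve(6.0)))
    d_sn, lf_reward = _draw_sequence_constants(rng)
    ratio = float(rng.uniform(lo, hi))
    sn_reward = _sn_reward_from_ratio(ratio, lf_reward)
    intervals = list(SEQUENCE_INTERVAL_GRID if direction == LF_TO_SN else SEQUENCE_INTERVAL_GRID[::-1])
    if d_sn + max(intervals) > DISTANCE_RANGE[1]:
        raise DesignInfeasibleError("LF distance would exceed the board range")
    trials = [
        Trial(
            sn=Option(reward=sn_reward, distance=d_sn),
            lf=Option(reward=lf_reward, distance=d_sn + i),
        )
        for i in intervals
    ]
    target_m = np.array([ratio - curve(i) for i in intervals])
    return Sequence(
        "distance", direction, trials, target_m=target_m, target_ratio=np.full(12, ratio)
    )


def generate_combined_sequence(
    profile: ParticipantProfile, direction: str, rng: np.random.Generator
) -> Sequence:
    """Combined block sequence: LF distance and SN reward both change.

    Per schedule point an interval is drawn from the set at which that
    manipulation is valid; the SN reward then realises ``p*(I_t) + m_t``.
    """
    sched = _directed_schedule(direction)
    curve = indifference_curve(profile)
    d_sn, lf_reward = _draw_sequence_constants(rng)
    trials = []
    ratios = np.empty(N_SCHEDULE_STEPS)
    for t, m in enumerate(sched):
        options = valid_intervals(profile, float(m))
        ivl = int(rng.choice(options))
        ratios[t] = curve(ivl) + m
        trials.append(
            Trial(
                sn=Option(reward=_sn_reward_from_ratio(ratios[t], lf_reward), distance=d_sn),
                lf=Option(reward=lf_reward, distance=d_sn + ivl),
            )
        )
    return Sequence("combined", direction, trials, target_m=sched.copy(), target_ratio=ratios)


_SEQUENCE_GENERATORS = {
    "distance": generate_distance_sequence,
    "reward": generate_value_sequence,
    "combined": generate_combined_sequence,
}


def generate_block(
    kind: str, profile: ParticipantProfile, rng: np.random.Generator
) -> BlockDesign:
    """An experimental block: 8 sequences per direction, order shuffled."""
    if kind not in _SEQUENCE_GENERATORS:
        raise ValueError(f"unknown block kind {kind!r}; expected one of {BLOCK_KINDS}")
    gen = _SEQUENCE_GENERATORS[kind]
    sequences = []
    for direction in (SN_TO_LF, LF_TO_SN):
        for _ in range(SEQUENCES_PER_DIRECTION):
            sequences.append(gen(profile, direction, rng))
    order = rng.permutation(len(sequences))
    return BlockDesign(block_kind=kind, sequences=[sequences[i] for i in order])
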