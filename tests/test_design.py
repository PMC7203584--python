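import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from attractorchoice.design import (
    INTERVAL_LEVELS,
    LF_TO_SN,
    RATIO_LEVELS,
    SN_DISTANCE_LEVELS,
    SN_TO_LF,
    DesignInfeasibleError,
    fit_indifference_points,
    fit_logistic_psychometric,
    generate_assessment_block,
    generate_assessment_set,
    generate_block,
    generate_combined_sequence,
    generate_distance_sequence,
    generate_value_sequence,
    indifference_curve,
    manipulation_schedule,
    valid_intervals,
)
from attractorchoice.valuation import ParticipantProfile, manipulation_point


# ---------------------------------------------------------------------------
# manipulation schedule
# ---------------------------------------------------------------------------

def test_schedule_matches_published_step_list():
    sched = manipulation_schedule()
    published = [
        -0.3000, -0.2455, -0.1909, -0.1364, -0.0818, -0.0273,
        0.0273, 0.0818, 0.1364, 0.1909, 0.2455, 0.3000,
    ]
    assert len(sched) == 12
    assert np.round(sched, 4).tolist() == published


def test_schedule_antisymmetric():
    sched = manipulation_schedule()
    assert np.allclose(sched, -sched[::-1])


# ---------------------------------------------------------------------------
# assessment factorial
# ---------------------------------------------------------------------------

def test_assessment_set_covers_full_factorial(rng):
    trials = generate_assessment_set(rng)
    assert len(trials) == 64
    cells = set()
    for t in trials:
        ratio = t.sn.reward / t.lf.reward
        # recover the designed ratio level (rounding moves it by < 0.5/55)
        level = min(RATIO_LEVELS, key=lambda r: abs(r - ratio))
        cells.add((level, t.sn.distance, t.lf.distance - t.sn.distance))
    assert cells == set(itertools.product(RATIO_LEVELS, SN_DISTANCE_LEVELS, INTERVAL_LEVELS))


def test_assessment_rewards_and_distances_in_range(rng):
    for trials in generate_assessment_block(rng, n_sets=5).sets:
        for t in trials:
            assert 55 <= t.lf.reward <= 99
            assert 1 <= t.sn.reward < t.lf.reward
            assert 2 <= t.sn.distance <= 3
            assert t.lf.distance <= 15


def test_assessment_block_size_and_reproducibility():
    a = generate_assessment_block(np.random.default_rng(5)).to_frame()
    b = generate_assessment_block(np.random.default_rng(5)).to_frame()
    assert len(a) == 320
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# indifference-point fitting
# ---------------------------------------------------------------------------

def _simulate_choices(rng, p_star, slope, n_per_level, levels=RATIO_LEVELS):
    ratios = np.repeat(levels, n_per_level)
    y = rng.random(ratios.size) < expit(slope * (ratios - p_star))
    return ratios, y.astype(float)


def test_logistic_fit_recovers_generating_inflection(rng):
    """Mean recovery error of the inflection at 160 choices per fit."""
    errs = []
    for _ in range(20):
        ratios, y = _simulate_choices(rng, p_star=0.70, slope=8.0, n_per_level=20)
        fit = fit_logistic_psychometric(ratios, y)
        assert fit["b"] > 0
        errs.append(abs(fit["p_star"] - 0.70))
    assert np.mean(errs) < 0.03


def test_logistic_fit_step_data_matches_grid_search_oracle():
    """Perfectly separated step data: penalized ML vs a brute-force grid.

    The inflection must land inside the gap between the last LF and first
    SN ratio level, and agree with an exhaustive likelihood grid.
    """
    ratios = np.repeat(RATIO_LEVELS, 10)
    y = (ratios > 0.75).astype(float)  # LF below 0.8, SN at and above
    fit = fit_logistic_psychometric(ratios, y)
    assert fit["separated"]
    assert 0.70 < fit["p_star"] < 0.80

    # oracle: maximize the same penalized likelihood on a dense grid
    a_grid = np.linspace(-80, 80, 321)
    b_grid = np.linspace(1, 100, 199)
    best = (math.inf, None, None)
    for b in b_grid:
        z = a_grid[:, None] + b * ratios[None, :]
        nll = np.logaddexp(0.0, z).sum(axis=1) - (y[None, :] * z).sum(axis=1)
        nll = nll + 1e-4 * (a_grid**2 + b**2)
        i = int(np.argmin(nll))
        if nll[i] < best[0]:
            best = (nll[i], a_grid[i], b)
    p_oracle = -best[1] / best[2]
    assert fit["p_star"] == pytest.approx(p_oracle, abs=0.02)


def test_logistic_fit_symmetric_coinflips_give_half(rng):
    ratios = np.repeat(np.linspace(0.2, 0.8, 7), 40)
    y = (np.arange(ratios.size) % 2).astype(float)  # exactly 50 % SN per level
    fit = fit_logistic_psychometric(ratios, y)
    assert fit["p_star"] == pytest.approx(0.5, abs=0.05)


def test_fit_indifference_points_parameter_recovery(rng):
    frames = []
    truth = {1: 0.9, 4: 0.75, 8: 0.6, 12: 0.5}
    for ivl, p in truth.items():
        ratios, y = _simulate_choices(rng, p_star=p, slope=12.0, n_per_level=20)
        frames.append(
            pd.DataFrame(
                {
                    "interval": ivl,
                    "reward_ratio": ratios,
                    "choice": np.where(y == 1, "SN", "LF"),
                }
            )
        )
    prof = fit_indifference_points(pd.concat(frames))
    assert not prof.flagged
    for ivl, p in truth.items():
        assert prof.indifference_points[ivl] == pytest.approx(p, abs=0.04)


def test_fit_flags_uninformative_choices():
    frame = pd.DataFrame(
        {
            "interval": np.repeat([1, 4, 8, 12], 40),
            "reward_ratio": np.tile(np.repeat(RATIO_LEVELS, 5), 4),
            "choice": "SN",  # one option only, at every interval
        }
    )
    prof = fit_indifference_points(frame)
    assert prof.flagged
    assert prof.indifference_points == {}


def test_indifference_curve_is_the_profile_interpolant(profile):
    curve = indifference_curve(profile)
    assert curve(8) == pytest.approx(0.55)
    assert curve(6) == pytest.approx(profile.p_star(6))
    with pytest.raises(ValueError):
        indifference_curve(ParticipantProfile(indifference_points={4: 0.6}))


# ---------------------------------------------------------------------------
# valid intervals
# ---------------------------------------------------------------------------

def test_valid_intervals_boundary_arithmetic():
    prof = ParticipantProfile(indifference_points={1: 0.8, 12: 0.8})
    # p* + 0.3 = 1.1 >= 1: nothing valid, must raise and name m
    with pytest.raises(DesignInfeasibleError, match=r"\+0\.3"):
        valid_intervals(prof, +0.3)
    prof_low = ParticipantProfile(indifference_points={1: 0.25, 12: 0.25})
    with pytest.raises(DesignInfeasibleError):
        valid_intervals(prof_low, -0.3)
    # m = 0: every interval with p* strictly inside (0, 1)
    assert valid_intervals(prof, 0.0) == list(range(1, 13))


def test_valid_intervals_mixed_profile(profile):
    # p* ranges 0.90 (I=1) .. 0.45 (I=12); m=+0.3 excludes the high end
    ok = valid_intervals(profile, +0.3)
    assert all(profile.p_star(i) + 0.3 < 1.0 for i in ok)
    assert 1 not in ok and 12 in ok


# ---------------------------------------------------------------------------
# sequence generators
# ---------------------------------------------------------------------------

def test_value_sequence_round_trip_and_constancy(profile, rng):
    seq = generate_value_sequence(profile, SN_TO_LF, rng)
    # only the SN reward varies within the sequence
    assert len({t.lf.reward for t in seq.trials}) == 1
    assert len({t.lf.distance for t in seq.trials}) == 1
    assert len({t.sn.distance for t in seq.trials}) == 1
    # monotone schedule x fixed LF reward: SN reward non-increasing
    rewards = [t.sn.reward for t in seq.trials]
    assert all(a >= b for a, b in zip(rewards, rewards[1:]))
    # pre-rounding round trip reproduces the schedule exactly
    ivl = seq.trials[0].lf.distance - seq.trials[0].sn.distance
    m_back = seq.target_ratio - profile.p_star(ivl)
    assert np.max(np.abs(m_back - seq.target_m)) < 1e-12
    # post-rounding, realised m within half a credit of the LF reward
    lf_reward = seq.trials[0].lf.reward
    m_real = np.array([manipulation_point(t, profile) for t in seq.trials])
    assert np.max(np.abs(m_real - seq.target_m)) <= 0.5 / lf_reward + 1e-12


def test_distance_sequence_structure(profile, rng):
    seq = generate_distance_sequence(profile, LF_TO_SN, rng)
    # only the LF distance varies
    assert len({t.sn.reward for t in seq.trials}) == 1
    assert len({t.lf.reward for t in seq.trials}) == 1
    intervals = [t.lf.distance - t.sn.distance for t in seq.trials]
    assert sorted(intervals) == list(range(1, 13))
    assert intervals == sorted(intervals)  # ascending for LF_to_SN
    # increasing distance makes LF worse: post-hoc m non-decreasing
    assert all(a <= b for a, b in zip(seq.target_m, seq.target_m[1:]))
    # drawn ratio lies between the medium-interval indifference points
    lo, hi = sorted((profile.p_star(7), profile.p_star(6)))
    assert lo <= seq.target_ratio[0] <= hi


def test_combined_sequence_round_trip(profile, rng):
    seq = generate_combined_sequence(profile, LF_TO_SN, rng)
    intervals = [t.lf.distance - t.sn.distance for t in seq.trials]
    m_back = np.array(
        [r - profile.p_star(i) for r, i in zip(seq.target_ratio, intervals)]
    )
    assert np.max(np.abs(m_back - seq.target_m)) < 1e-12
    sched = manipulation_schedule()
    assert np.allclose(seq.target_m, sched)


def test_combined_sequence_varies_both_features(profile):
    # across enough draws both LF distance and SN reward vary within sequences
    rng = np.random.default_rng(0)
    varied_distance = varied_reward = False
    for _ in range(10):
        seq = generate_combined_sequence(profile, SN_TO_LF, rng)
        varied_distance |= len({t.lf.distance for t in seq.trials}) > 1
        varied_reward |= len({t.sn.reward for t in seq.trials}) > 1
    assert varied_distance and varied_reward


def test_value_sequence_requires_feasible_interval(rng):
    prof = ParticipantProfile(indifference_points={1: 0.95, 12: 0.85})
    with pytest.raises(DesignInfeasibleError):
        generate_value_sequence(prof, SN_TO_LF, rng)


# ---------------------------------------------------------------------------
# block assembly
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind", ["distance", "reward", "combined"])
def test_block_counts_and_balance(kind, profile):
    block = generate_block(kind, profile, np.random.default_rng(3))
    assert len(block.sequences) == 16
    assert block.n_trials == 192
    directions = [s.direction for s in block.sequences]
    assert directions.count(SN_TO_LF) == directions.count(LF_TO_SN) == 8
    frame = block.to_frame()
    assert len(frame) == 192
    assert set(frame["sequence_id"]) == set(range(16))


def test_block_reproducible_given_seed(profile):
    a = generate_block("combined", profile, np.random.default_rng(9)).to_frame()
    b = generate_block("combined", profile, np.random.default_rng(9)).to_frame()
    pd.testing.assert_frame_equal(a, b)


def test_generated_trials_satisfy_task_invariants(profile):
    rng = np.random.default_rng(11)
    for kind in ("distance", "reward", "combined"):
        frame = generate_block(kind, profile, rng).to_frame()
        assert frame["sn_reward"].between(1, 99).all()
        assert frame["lf_reward"].between(55, 99).all()
        assert (frame["sn_reward"] < frame["lf_reward"]).all()
        assert frame["sn_distance"].between(2, 3).all()
        assert frame["lf_distance"].between(3, 15).all()
        assert (frame["interval"] >= 1).all()
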