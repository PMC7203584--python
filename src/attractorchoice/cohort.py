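"""Synthetic participants and cohorts.

Replaces the human sample: each synthetic participant owns a hyperbolic
discount rate drawn from a log-normal across the cohort, runs through the
assessment block, has indifference points fitted from those choices, gets
individually tailored experimental blocks generated from the *fitted*
profile, and then produces choices in them — while the chooser itself acts
on the participant's *true* valuation.  Three chooser families are
available:

* ``logistic`` / ``lagged-logistic``: memoryless or lag-one logistic in the
  manipulation point — the null (b = 0) and simple alternative (b > 0)
  generative models for calibration and recovery tests;
* ``attractor``: the double-well dynamics with inter-trial carryover;
* ``pcs``: the parallel-constraint-satisfaction network.

Participants whose assessment choices cannot support the sequential
manipulation are flagged and replaced, just as such volunteers would be
excluded from an experimental sample.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from . import attractor as attractor_mod
from . import pcs as pcs_mod
from .attractor import AttractorParams
from .design import (
    BLOCK_KINDS,
    DesignInfeasibleError,
    fit_indifference_points,
    generate_assessment_block,
    generate_block,
)
from .pcs import PCSParams
from .valuation import (
    ParticipantProfile,
    analytic_indifference_point,
    control_parameter,
    reference_indifference_point,
)

__all__ = [
    "SyntheticCohort",
    "CohortDataset",
    "InfeasibleParticipantError",
    "lagged_logistic_choice",
    "simulate_participant",
    "simulate_cohort",
]

RECORD_COLUMNS = [
    "participant",
    "block",
    "block_kind",
    "block_order",
    "sequence_id",
    "trial_idx",
    "direction",
    "sn_reward",
    "sn_distance",
    "lf_reward",
    "lf_distance",
    "reward_ratio",
    "interval",
    "manipulation_point",
    "true_manipulation_point",
    "choice",
    "rt",
    "end_x",
]


class InfeasibleParticipantError(RuntimeError):
    """Assessment behaviour does not allow the sequential manipulation."""


@dataclass(frozen=True)
class SyntheticCohort:
    """Configuration of a synthetic cohort.

    Discount rates are log-normal across participants (median 0.15,
    log-scale sd 0.4), chosen so that indifference points at the design
    intervals fall inside the assessment ratio range for nearly all draws.
    The time-limited assessment block is emulated as a fixed count of 134
    trials, a typical yield of an 8-minute block.
    """

    n_participants: int = 40
    chooser_kind: str = "attractor"
    sensitivity: float = 8.0
    perseveration_weight: float = 0.0
    discount_log_mean: float = math.log(0.15)
    discount_log_sd: float = 0.4
    n_assessment_trials: int = 134
    master_seed: int = 0
    attractor_params: AttractorParams = field(default_factory=AttractorParams)
    pcs_params: PCSParams = field(default_factory=PCSParams)
    max_replacements: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.chooser_kind not in ("logistic", "lagged-logistic", "attractor", "pcs"):
            raise ValueError(f"unknown chooser_kind {self.chooser_kind!r}")
        if self.sensitivity <= 0 or self.perseveration_weight < 0:
            raise ValueError("need sensitivity > 0 and perseveration_weight >= 0")


@dataclass
class CohortDataset:
    """All trial records of a cohort plus its ground-truth manifest."""

    records: pd.DataFrame
    manifest: pd.DataFrame
    profiles: Dict[int, ParticipantProfile]
    n_replaced: int = 0


def lagged_logistic_choice(
    m: float,
    last_choice: Optional[str],
    s: float,
    b: float,
    rng: np.random.Generator,
) -> str:
    """One lag-one logistic choice: ``P(SN) = expit(s m + b h)``.

    ``h`` is +1 after an SN choice, -1 after LF, 0 with no history.  With
    ``b = 0`` the rule is memoryless — the null model under which the
    perseveration index is centred at zero.
    """
    if s <= 0 or b < 0:
        raise ValueError("need s > 0 and b >= 0")
    h = {None: 0.0, "SN": 1.0, "LF": -1.0}[last_choice]
    p_sn = expit(s * m + b * h)
    return "SN" if rng.random() < p_sn else "LF"


def _true_manipulation_points(frame: pd.DataFrame, discount_rate: float) -> np.ndarray:
    """m under the participant's true preferences, from realised integer rewards.

    The true indifference-point curve is taken as a function of the interval
    (pooled over the two SN distances), matching the profile-based
    definition of the manipulation point.
    """
    r = frame["sn_reward"].to_numpy(float) / frame["lf_reward"].to_numpy(float)
    p = np.array(
        [reference_indifference_point(discount_rate, i) for i in frame["interval"]]
    )
    return r - p


def _choose_logistic(
    frame: pd.DataFrame, m_true: np.ndarray, s: float, b: float, rng: np.random.Generator
) -> pd.DataFrame:
    choices: List[str] = []
    last: Optional[str] = None
    for m in m_true:
        c = lagged_logistic_choice(float(m), last, s, b, rng)
        choices.append(c)
        last = c
    out = frame.copy()
    out["choice"] = choices
    out["rt"] = np.nan
    out["end_x"] = np.nan
    return out


def _choose_attractor(
    frame: pd.DataFrame, m_true: np.ndarray, params: AttractorParams, seed: int
) -> pd.DataFrame:
    out = frame.copy()
    out["_m_true"] = m_true
    out = attractor_mod.simulate_block(out, params, seed=seed, m_column="_m_true")
    return out.drop(columns=["_m_true"])


def _choose_pcs(
    frame: pd.DataFrame, params: PCSParams, rng: np.random.Generator
) -> pd.DataFrame:
    from .valuation import Option, Trial

    choices, iters = [], []
    carry: Optional[np.ndarray] = None
    for row in frame.itertuples():
        trial = Trial(
            sn=Option(int(row.sn_reward), int(row.sn_distance)),
            lf=Option(int(row.lf_reward), int(row.lf_distance)),
        )
        res = pcs_mod.pcs_decide(trial, params, carryover=carry, rng=rng)
        choices.append(res["choice"])
        iters.append(res["iterations"])
        carry = res["option_activations"] * params.retention
    out = frame.copy()
    out["choice"] = choices
    out["rt"] = np.asarray(iters, dtype=float)  # iterations-to-stability as RT proxy
    out["end_x"] = np.nan
    return out


def _simulate_choices(
    frame: pd.DataFrame,
    discount_rate: float,
    cohort: SyntheticCohort,
    seed_seq: np.random.SeedSequence,
) -> pd.DataFrame:
    """Dispatch a trial frame to the configured chooser."""
    m_true = _true_manipulation_points(frame, discount_rate)
    rng = np.random.default_rng(seed_seq)
    if cohort.chooser_kind in ("logistic", "lagged-logistic"):
        b = cohort.perseveration_weight if cohort.chooser_kind == "lagged-logistic" else 0.0
        out = _choose_logistic(frame, m_true, cohort.sensitivity, b, rng)
    elif cohort.chooser_kind == "attractor":
        out = _choose_attractor(
            frame, m_true, cohort.attractor_params, seed=int(rng.integers(2**31))
        )
    else:
        out = _choose_pcs(frame, cohort.pcs_params, rng)
    out["true_manipulation_point"] = m_true
    return out


_BLOCK_ORDERS = list(itertools.permutations(BLOCK_KINDS))


def simulate_participant(
    participant_id: int,
    discount_rate: float,
    cohort: SyntheticCohort,
    seed: np.random.SeedSequence,
    block_order: Tuple[str, ...] = BLOCK_KINDS,
) -> Tuple[pd.DataFrame, ParticipantProfile]:
    """Run one participant through assessment and the three experimental blocks.

    The assessment design and choices come first; indifference points are
    fitted from those choices; the experimental blocks are generated from
    the fitted profile and simulated in the given block order with the
    carryover state reset at each block boundary.  Deterministic given
    ``seed``.  Raises :class:`InfeasibleParticipantError` if the fitted
    profile is flagged or design generation fails.
    """
    design_seq, assess_seq, *block_seqs = seed.spawn(2 + len(block_order))
    design_rng = np.random.default_rng(design_seq)

    n_sets = max(5, math.ceil(cohort.n_assessment_trials / 64))
    assess = generate_assessment_block(design_rng, n_sets=n_sets).to_frame()
    assess = assess.iloc[: cohort.n_assessment_trials].reset_index(drop=True)
    assess = _simulate_choices(assess, discount_rate, cohort, assess_seq)
    assess["block_kind"] = "assessment"
    assess["block_order"] = -1

    profile = fit_indifference_points(assess)
    profile.discount_rate = discount_rate
    if profile.flagged:
        raise InfeasibleParticipantError(
            f"participant {participant_id}: {profile.flag_reason}"
        )

    frames = [assess]
    for order_idx, (kind, bseq) in enumerate(zip(block_order, block_seqs)):
        try:
            block = generate_block(kind, profile, design_rng)
        except DesignInfeasibleError as err:
            raise InfeasibleParticipantError(
                f"participant {participant_id}: {err}"
            ) from err
        frame = _simulate_choices(block.to_frame(), discount_rate, cohort, bseq)
        frame["block_kind"] = kind
        frame["block_order"] = order_idx
        frames.append(frame)

    records = pd.concat(frames, ignore_index=True)
    records["participant"] = participant_id
    return records[RECORD_COLUMNS], profile


def simulate_cohort(cohort: SyntheticCohort) -> CohortDataset:
    """Simulate a full cohort with balanced block orders.

    Per-participant randomness comes from substreams spawned
    deterministically from ``master_seed``.  Block orders cycle through the
    six permutations of the three experimental blocks.  Infeasible
    participants are replaced by fresh draws (new substream), up to a cap.
    """
    root = np.random.SeedSequence(cohort.master_seed)
    max_attempts = cohort.max_replacements
    if max_attempts is None:
        max_attempts = 3 * cohort.n_participants
    all_records: List[pd.DataFrame] = []
    manifest_rows: List[dict] = []
    profiles: Dict[int, ParticipantProfile] = {}
    accepted = 0
    attempts = 0
    n_replaced = 0
    while accepted < cohort.n_participants:
        if attempts >= cohort.n_participants + max_attempts:
            raise RuntimeError(
                f"could not assemble {cohort.n_participants} feasible participants "
                f"after {attempts} attempts"
            )
        sub = root.spawn(1)[0]
        attempts += 1
        k = float(
            np.random.default_rng(sub.spawn(1)[0]).lognormal(
                cohort.discount_log_mean, cohort.discount_log_sd
            )
        )
        order = _BLOCK_ORDERS[accepted % len(_BLOCK_ORDERS)]
        try:
            records, profile = simulate_participant(
                accepted, k, cohort, sub, block_order=order
            )
        except InfeasibleParticipantError:
            n_replaced += 1
            continue
        all_records.append(records)
        profiles[accepted] = profile
        row = {
            "participant": accepted,
            "discount_rate": k,
            "chooser_kind": cohort.chooser_kind,
            "block_order": "|".join(order),
        }
        for ivl in (1, 4, 8, 12):
            row[f"true_p_star_{ivl}"] = reference_indifference_point(k, ivl)
            row[f"fitted_p_star_{ivl}"] = profile.indifference_points.get(ivl, np.nan)
        manifest_rows.append(row)
        accepted += 1
    return CohortDataset(
        records=pd.concat(all_records, ignore_index=True),
        manifest=pd.DataFrame(manifest_rows),
        profiles=profiles,
        n_replaced=n_replaced,
    )
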