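"""Perseveration statistics from trial logs.

The perseveration index (PI) of a participant in a block is the difference
between their SN-choice ratios in the two sequence directions,

    PI = P(SN | SN_to_LF) - P(SN | LF_to_SN),

which is positive when choices stick with the option that was superior at
the start of a sequence.  Direction-split choice curves (% LF choices per
manipulation-point bin or per interval) expose the same effect at a finer
grain: under perseveration the two directions' curves separate in the
mid-schedule bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .design import LF_TO_SN, SN_TO_LF

__all__ = [
    "AnalysisError",
    "OneSampleResult",
    "perseveration_index",
    "perseveration_table",
    "perseveration_curves",
    "one_sample_test",
    "summarize_block",
    "compare_blocks",
]

logger = logging.getLogger(__name__)

_VALID_CHOICES = ("SN", "LF")


class AnalysisError(ValueError):
    """Raised when a statistic is undefined for the given records."""


def _sn_ratio(frame: pd.DataFrame) -> float:
    valid = frame[frame["choice"].isin(_VALID_CHOICES)]
    if len(valid) == 0:
        raise AnalysisError("no valid (non-timeout) trials in one direction")
    return float((valid["choice"] == "SN").mean())


def perseveration_index(records: pd.DataFrame) -> float:
    """PI of one participant-block: SN ratio difference between directions.

    Timeouts are excluded from both ratios.  Raises
    :class:`AnalysisError` if either direction has no valid trial.
    """
    directions = set(records["direction"])
    if not {SN_TO_LF, LF_TO_SN} <= directions:
        raise AnalysisError(f"records must contain both directions, have {directions}")
    p_sn_to_lf = _sn_ratio(records[records["direction"] == SN_TO_LF])
    p_lf_to_sn = _sn_ratio(records[records["direction"] == LF_TO_SN])
    return p_sn_to_lf - p_lf_to_sn


def perseveration_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per participant x experimental block PI, wide format.

    Participants for whom a block's PI is undefined get NaN there.
    """
    rows = {}
    exp = records[records["block_kind"].isin(("distance", "reward", "combined"))]
    for (pid, kind), grp in exp.groupby(["participant", "block_kind"]):
        try:
            rows.setdefault(pid, {})[kind] = perseveration_index(grp)
        except AnalysisError:
            rows.setdefault(pid, {})[kind] = math.nan
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "participant"
    return table


def perseveration_curves(
    records: pd.DataFrame,
    block_kind: str,
    key: str = "manipulation_point",
    n_bins: Optional[int] = None,
    decimals: int = 4,
) -> pd.DataFrame:
    """Direction-split mean %LF-choice curves with standard errors.

    Per direction and bin, the %LF choice is first averaged within each
    participant and then across participants (SE across participants).  For
    the reward and combined blocks ``key='manipulation_point'`` bins on the
    scheduled values (rounded to ``decimals``); for the distance block use
    ``key='interval'``, or pass ``n_bins`` to bin a continuous key (e.g. the
    post-hoc manipulation points) into equal-width bins.  Empty bins are
    omitted with a warning.
    """
    sub = records[
        (records["block_kind"] == block_kind) & records["choice"].isin(_VALID_CHOICES)
    ].copy()
    if len(sub) == 0:
        raise AnalysisError(f"no valid records for block {block_kind!r}")
    if n_bins is not None:
        edges = np.linspace(sub[key].min(), sub[key].max(), n_bins + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        idx = np.clip(np.digitize(sub[key], edges[1:-1]), 0, n_bins - 1)
        sub["bin"] = mids[idx]
    else:
        sub["bin"] = sub[key].round(decimals)
    sub["is_lf"] = (sub["choice"] == "LF").astype(float) * 100.0

    per_part = (
        sub.groupby(["direction", "bin", "participant"])["is_lf"].mean().reset_index()
    )
    rows = []
    for (direction, b), grp in per_part.groupby(["direction", "bin"]):
        vals = grp["is_lf"].to_numpy()
        if vals.size == 0:
            logger.warning("empty bin %s in direction %s omitted", b, direction)
            continue
        rows.append(
            {
                "direction": direction,
                "bin": b,
                "pct_lf": float(vals.mean()),
                "se": float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan,
                "n_participants": int(vals.size),
            }
        )
    return pd.DataFrame(rows).sort_values(["direction", "bin"]).reset_index(drop=True)


@dataclass(frozen=True)
class OneSampleResult:
    """One-sided (> 0) one-sample t test with Cohen's d."""

    mean: float
    sd: float
    t: float
    df: int
    p: float
    cohen_d: float


def one_sample_test(indices: Iterable[float]) -> OneSampleResult:
    """Test whether perseveration indices exceed zero.

    ``t = mean / (sd / sqrt(n))``, ``d = mean / sd``, p from the upper tail
    of the t distribution with n - 1 df.  Requires n >= 2 and nonzero
    variance.
    """
    x = np.asarray(list(indices), dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise AnalysisError(f"need >= 2 indices, have {x.size}")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise AnalysisError("zero variance among indices")
    mean = float(x.mean())
    t = mean / (sd / math.sqrt(x.size))
    df = x.size - 1
    p = float(stats.t.sf(t, df))
    return OneSampleResult(mean=mean, sd=sd, t=t, df=df, p=p, cohen_d=mean / sd)


def summarize_block(indices: Iterable[float]) -> dict:
    x = np.asarray(list(indices), dtype=float)
    x = x[~np.isnan(x)]
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else math.nan,
        "se": float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else math.nan,
    }


def compare_blocks(
    pi_table: pd.DataFrame, n_boot: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Descriptive block comparison with bootstrap intervals.

    Per-block mean, sd, SE plus pairwise mean differences with seeded
    bootstrap percentile intervals (resampling participants with
    replacement).  Purely descriptive: no inferential correction is applied.
    """
    rng = np.random.default_rng(seed)
    blocks = list(pi_table.columns)
    rows = []
    for b in blocks:
        s = summarize_block(pi_table[b])
        rows.append({"comparison": b, "mean": s["mean"], "sd": s["sd"], "se": s["se"],
                     "ci_lo": math.nan, "ci_hi": math.nan})
    clean = pi_table.dropna()
    n = len(clean)
    for i, a in enumerate(blocks):
        for b in blocks[i + 1:]:
            diff = clean[a].to_numpy() - clean[b].to_numpy()
            obs = float(diff.mean())
            idx = rng.integers(0, n, size=(n_boot, n))
            boots = diff[idx].mean(axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append(
                {
                    "comparison": f"{a} - {b}",
                    "mean": obs,
                    "sd": float(diff.std(ddof=1)),
                    "se": float(diff.std(ddof=1) / math.sqrt(n)),
                    "ci_lo": float(lo),
                    "ci_hi": float(hi),
                }
            )
    return pd.DataFrame(rows)
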