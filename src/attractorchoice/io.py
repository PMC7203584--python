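"""Plain-text serialization: trial logs (CSV), profiles and manifests (YAML)."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .cohort import CohortDataset
from .valuation import ParticipantProfile

__all__ = [
    "write_trial_log",
    "read_trial_log",
    "write_profile",
    "read_profile",
    "write_cohort",
    "read_cohort",
]

PathLike = Union[str, Path]


def write_trial_log(frame: pd.DataFrame, path: PathLike) -> None:
    """Comma-separated trial log with header row, one trial per row, UTF-8."""
    frame.to_csv(path, index=False)


def read_trial_log(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profile(profile: ParticipantProfile, path: PathLike) -> None:
    """Key-value profile file: fitted p* per interval plus fit diagnostics."""
    payload = {
        "indifference_points": {
            int(k): float(v) for k, v in profile.indifference_points.items()
        },
        "discount_rate": profile.discount_rate,
        "flagged": profile.flagged,
        "flag_reason": profile.flag_reason,
        "fit_info": {
            int(k): {kk: _plain(vv) for kk, vv in v.items()}
            for k, v in profile.fit_info.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")


def _plain(v):
    try:
        return v.item()  # numpy scalar
    except AttributeError:
        return v


def read_profile(path: PathLike) -> ParticipantProfile:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return ParticipantProfile(
        indifference_points={int(k): float(v) for k, v in payload["indifference_points"].items()},
        discount_rate=payload.get("discount_rate"),
        flagged=payload.get("flagged", False),
        flag_reason=payload.get("flag_reason", ""),
        fit_info={int(k): dict(v) for k, v in payload.get("fit_info", {}).items()},
    )


def write_cohort(dataset: CohortDataset, outdir: PathLike) -> None:
    """Dataset directory: per-participant trial logs plus a cohort manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, grp in dataset.records.groupby("participant"):
        write_trial_log(grp, out / f"participant_{pid:03d}.csv")
    dataset.manifest.to_csv(out / "manifest.csv", index=False)
    meta = {"n_participants": int(dataset.manifest.shape[0]), "n_replaced": dataset.n_replaced}
    (out / "cohort.yaml").write_text(yaml.safe_dump(meta), encoding="utf-8")
    profiles_dir = out / "profiles"
    profiles_dir.mkdir(exist_ok=True)
    for pid, profile in dataset.profiles.items():
        write_profile(profile, profiles_dir / f"participant_{pid:03d}.yaml")


def read_cohort(outdir: PathLike) -> CohortDataset:
    out = Path(outdir)
    logs = sorted(out.glob("participant_*.csv"))
    records = pd.concat([read_trial_log(p) for p in logs], ignore_index=True)
    manifest = pd.read_csv(out / "manifest.csv")
    meta = yaml.safe_load((out / "cohort.yaml").read_text(encoding="utf-8"))
    profiles = {}
    for p in sorted((out / "profiles").glob("participant_*.yaml")):
        pid = int(p.stem.split("_")[1])
        profiles[pid] = read_profile(p)
    return CohortDataset(
        records=records,
        manifest=manifest,
        profiles=profiles,
        n_replaced=int(meta.get("n_replaced", 0)),
    )
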