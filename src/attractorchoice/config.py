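"""Structured-text (YAML) run configuration.

A config file has up to three sections, all optional::

    attractor:
      noise_sd: 0.35
      threshold: 0.8
      tau_iti: 2.0
    pcs:
      w_validity_distance: 0.10
      w_validity_reward: 0.10
    cohort:
      n_participants: 40
      chooser_kind: attractor
      master_seed: 1

Unknown keys raise immediately rather than being silently ignored.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import yaml

from .attractor import AttractorParams
from .cohort import SyntheticCohort
from .pcs import PCSParams

__all__ = ["load_config", "cohort_from_config"]


def _build(cls, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise KeyError(f"unknown keys in [{name}] section: {sorted(unknown)}")
    return cls(**section)


def load_config(path: Union[str, Path]) -> dict:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    for section in raw:
        if section not in ("attractor", "pcs", "cohort"):
            raise KeyError(f"unknown config section {section!r}")
    return raw


def cohort_from_config(path: Union[str, Path], seed=None) -> SyntheticCohort:
    """Build a :class:`SyntheticCohort` from a config file.

    ``seed`` (e.g. a CLI flag) overrides any ``master_seed`` in the file.
    """
    raw = load_config(path)
    attractor = _build(AttractorParams, raw.get("attractor", {}), "attractor")
    pcs = _build(PCSParams, raw.get("pcs", {}), "pcs")
    cohort_kwargs = dict(raw.get("cohort", {}))
    if seed is not None:
        cohort_kwargs["master_seed"] = int(seed)
    cohort_kwargs["attractor_params"] = attractor
    cohort_kwargs["pcs_params"] = pcs
    return _build(SyntheticCohort, cohort_kwargs, "cohort")
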