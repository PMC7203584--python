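"""Parallel constraint satisfaction (PCS) network chooser.

A hierarchical alternative to the one-dimensional attractor: a small
interactive-activation network with a clamped general-validity node, four
feature nodes (SN/LF distance and SN/LF reward) and two mutually inhibiting
option nodes.  The validity node drives the feature layer; the strength of
that drive per layer (``w_validity_distance``, ``w_validity_reward``)
encodes feature importance.  Feature evidence enters through signed
feature-option weights proportional to min-max scaled feature values.
The network iterates until the change of the energy (the weighted sum of
activation products) falls below a stability threshold; the option node
with the higher activation is the response.  Residual option activations,
shrunk by a retention factor over the inter-trial interval, carry over into
the next trial and produce perseveration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .valuation import DISTANCE_RANGE, REWARD_RANGE, Trial

__all__ = [
    "PCSParams",
    "PCSNetwork",
    "scale_reward",
    "scale_distance",
    "build_trial_network",
    "pcs_step",
    "pcs_energy",
    "pcs_run",
    "pcs_decide",
]

# node indices
VALIDITY, D_SN, D_LF, R_SN, R_LF, OPT_SN, OPT_LF = range(7)
N_NODES = 7
FLOOR, CEILING = -1.0, 1.0


@dataclass(frozen=True)
class PCSParams:
    """Weights and dynamics of the PCS network.

    ``w_validity_distance`` / ``w_validity_reward`` are the importance
    weights of the two feature layers; equal values make the network treat
    distances and rewards symmetrically.  ``retention`` is the fraction of
    post-decision option activation surviving the inter-trial interval
    (default mirrors the attractor's ITI relaxation, exp(-1.3 / 2.0)).
    ``input_noise_sd`` jitters the scaled feature values per trial so that
    choices near indifference are stochastic.
    """

    w_validity_distance: float = 0.10
    w_validity_reward: float = 0.10
    w_feature_option: float = 0.10
    w_inhibition: float = -0.05
    decay: float = 0.10
    stability_threshold: float = 1e-5
    max_iters: int = 500
    retention: float = math.exp(-1.3 / 2.0)
    input_noise_sd: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 < self.decay < 1.0):
            raise ValueError("decay must be in (0, 1)")
        if self.w_inhibition >= 0:
            raise ValueError("option-option weight must be negative (mutual inhibition)")
        if self.stability_threshold <= 0:
            raise ValueError("stability_threshold must be > 0")
        if not (0.0 <= self.retention < 1.0):
            raise ValueError("retention must be in [0, 1)")


@dataclass
class PCSNetwork:
    """Activations plus a symmetric weight matrix; validity is clamped to 1."""

    weights: np.ndarray
    activations: np.ndarray = field(
        default_factory=lambda: np.zeros(N_NODES, dtype=float)
    )
    decay: float = 0.10

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (N_NODES, N_NODES):
            raise ValueError(f"weight matrix must be {N_NODES}x{N_NODES}")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if self.weights[OPT_SN, OPT_LF] >= 0:
            raise ValueError("option nodes must inhibit each other")
        self.activations = np.asarray(self.activations, dtype=float).copy()
        self.activations[VALIDITY] = 1.0


def scale_reward(reward: float) -> float:
    """Min-max scale a reward from [1, 99] to [-1, 1]."""
    lo, hi = REWARD_RANGE
    return 2.0 * (reward - lo) / (hi - lo) - 1.0


def scale_distance(distance: float) -> float:
    """Min-max scale a distance from [2, 15] to [-1, 1], near = favourable."""
    lo, hi = DISTANCE_RANGE
    return 1.0 - 2.0 * (distance - lo) / (hi - lo)


def build_trial_network(
    trial: Trial,
    params: PCSParams,
    carryover: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> PCSNetwork:
    """Wire the network for one trial.

    The validity node excites every feature node with its layer's importance
    weight.  Each feature node links to its own option with a weight
    proportional to the scaled feature value (favourable features excite)
    and to the rival option with the opposite sign.  Option activations from
    a previous decision may be seeded through ``carryover``.
    """
    feats = np.array(
        [
            scale_distance(trial.sn.distance),
            scale_distance(trial.lf.distance),
            scale_reward(trial.sn.reward),
            scale_reward(trial.lf.reward),
        ]
    )
    if params.input_noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when input_noise_sd > 0")
        feats = feats + rng.normal(0.0, params.input_noise_sd, size=4)

    w = np.zeros((N_NODES, N_NODES))
    w[VALIDITY, D_SN] = w[VALIDITY, D_LF] = params.w_validity_distance
    w[VALIDITY, R_SN] = w[VALIDITY, R_LF] = params.w_validity_reward
    wf = params.w_feature_option
    for node, value, own in (
        (D_SN, feats[0], OPT_SN),
        (D_LF, feats[1], OPT_LF),
        (R_SN, feats[2], OPT_SN),
        (R_LF, feats[3], OPT_LF),
    ):
        rival = OPT_LF if own == OPT_SN else OPT_SN
        w[node, own] = wf * value
        w[node, rival] = -wf * value
    w[OPT_SN, OPT_LF] = params.w_inhibition
    w = w + w.T

    activations = np.zeros(N_NODES)
    if carryover is not None:
        activations[OPT_SN] = carryover[0]
        activations[OPT_LF] = carryover[1]
    return PCSNetwork(weights=w, activations=activations, decay=params.decay)


def pcs_step(net: PCSNetwork) -> PCSNetwork:
    """One synchronous interactive-activation update of all unclamped nodes.

    With net input ``n_i = sum_j w_ij a_j``:
    ``a_i <- a_i (1 - decay) + n_i (ceiling - a_i)`` for positive net input,
    ``a_i <- a_i (1 - decay) + n_i (a_i - floor)`` for negative; activations
    are kept inside [floor, ceiling] and the validity node stays at 1.
    """
    a = net.activations
    n = net.weights @ a
    grow = a * (1.0 - net.decay) + n * (CEILING - a)
    shrink = a * (1.0 - net.decay) + n * (a - FLOOR)
    new = np.where(n > 0, grow, shrink)
    new = np.clip(new, FLOOR, CEILING)
    new[VALIDITY] = 1.0
    return PCSNetwork(weights=net.weights, activations=new, decay=net.decay)


def pcs_energy(net: PCSNetwork) -> float:
    """Weighted sum of activation products over node pairs, ``sum_{i<j} w_ij a_i a_j``."""
    a = net.activations
    return 0.5 * float(a @ net.weights @ a)


def pcs_run(
    net: PCSNetwork, stability_threshold: float, max_iters: int
) -> Tuple[PCSNetwork, int, bool]:
    """Iterate until the energy change falls below threshold or iterations run out.

    Runs the :func:`pcs_step` update on raw arrays (identical arithmetic,
    without per-step object construction) for speed.
    """
    w = net.weights
    decay = net.decay
    a = net.activations.copy()
    e = 0.5 * float(a @ w @ a)
    stable = False
    it = max_iters
    for i in range(1, max_iters + 1):
        n = w @ a
        a = np.where(n > 0, a * (1.0 - decay) + n * (CEILING - a), a * (1.0 - decay) + n * (a - FLOOR))
        np.clip(a, FLOOR, CEILING, out=a)
        a[VALIDITY] = 1.0
        e_new = 0.5 * float(a @ w @ a)
        if abs(e_new - e) < stability_threshold:
            stable, it = True, i
            break
        e = e_new
    out = PCSNetwork(weights=w, activations=a, decay=decay)
    return out, it, stable


def pcs_decide(
    trial: Trial,
    params: PCSParams,
    carryover: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Settle the network on one trial and read out the response.

    Returns choice (``SN``/``LF``/``TIMEOUT`` when stability is not reached),
    iterations to stability, and the post-decision option activations for
    carryover into the next trial.  Exact activation ties are broken by a
    seeded coin flip and logged in the result.
    """
    net = build_trial_network(trial, params, carryover=carryover, rng=rng)
    net, iters, stable = pcs_run(net, params.stability_threshold, params.max_iters)
    a_sn, a_lf = net.activations[OPT_SN], net.activations[OPT_LF]
    tie = a_sn == a_lf
    if not stable:
        choice = "TIMEOUT"
    elif tie:
        if rng is None:
            raise ValueError("rng required to break an exact tie")
        choice = "SN" if rng.random() < 0.5 else "LF"
    else:
        choice = "SN" if a_sn > a_lf else "LF"
    return {
        "choice": choice,
        "iterations": iters,
        "stable": stable,
        "tie": bool(tie),
        "option_activations": np.array([a_sn, a_lf]),
    }
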