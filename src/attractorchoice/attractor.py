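"""One-dimensional stochastic attractor dynamics of binary choice.

The decision variable ``x`` evolves in a double-well potential

    V(x, c) = x^4 / 4 - x^2 / 2 - c * x

whose two minima are the decision states (``+x`` the SN option, ``-x`` the
LF option by convention).  The control parameter ``c`` tilts the landscape:
for ``c > 0`` the SN well is deeper (``V(1, c) - V(-1, c) = -2c``), making
the SN decision state more likely.  Within a trial the state follows the
overdamped Langevin equation

    dx = -V'(x, c) dt / tau_trial + sigma dW,

integrated by Euler–Maruyama, and a choice is read out when ``|x|`` crosses
the decision bound ``theta``.  During the inter-trial interval the stimulus
is off and the state relaxes linearly toward the neutral point,

    dx = -(x / tau_iti) dt + sigma_iti dW,

but the 1.3 s ITI is short against ``tau_iti``, so a residual bias toward
the previous attractor survives into the next trial.  That incomplete
relaxation is the mechanism of choice perseveration and hysteresis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _kernel
from .valuation import control_parameter

__all__ = [
    "SN",
    "LF",
    "TIMEOUT",
    "AttractorParams",
    "AttractorState",
    "TrialOutcome",
    "potential",
    "drift",
    "step",
    "relax_iti",
    "run_trial",
    "simulate_sequence",
    "simulate_block",
]

SN = "SN"
LF = "LF"
TIMEOUT = "TIMEOUT"

_CODE_TO_CHOICE = {_kernel.CHOICE_SN: SN, _kernel.CHOICE_LF: LF, _kernel.CHOICE_TIMEOUT: TIMEOUT}


@dataclass(frozen=True)
class AttractorParams:
    """Parameters of the within-trial and inter-trial dynamics.

    Attributes
    ----------
    noise_sd
        Diffusion strength sigma of the within-trial dynamics (per sqrt s).
    threshold
        Decision bound theta on ``|x|``, in (0, 1].
    dt
        Euler–Maruyama time step (s); must be small against both taus.
    tau_trial
        Time constant of the within-trial drift (s).
    tau_iti
        Time constant of the linear ITI relaxation (s).
    t_max
        Trial deadline (s); crossing later is recorded as a timeout.
    iti_duration
        Inter-trial interval (s); 1.3 s in the task.
    control_gain
        Linear gain mapping manipulation points onto c.
    ceiling
        Hard bound on ``|x|`` against numerical escape.
    iti_noise_sd
        Diffusion strength during the ITI; defaults to ``noise_sd``.
    """

    noise_sd: float = 0.35
    threshold: float = 0.8
    dt: float = 1e-3
    tau_trial: float = 0.1
    tau_iti: float = 2.0
    t_max: float = 10.0
    iti_duration: float = 1.3
    control_gain: float = 1.0
    ceiling: float = 1.5
    iti_noise_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.dt >= min(self.tau_trial, self.tau_iti):
            raise ValueError("dt must be small against tau_trial and tau_iti")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        if self.t_max <= 0 or self.iti_duration < 0:
            raise ValueError("t_max must be > 0 and iti_duration >= 0")
        if self.noise_sd < 0 or (self.iti_noise_sd is not None and self.iti_noise_sd < 0):
            raise ValueError("noise standard deviations must be >= 0")
        if self.ceiling < self.threshold:
            raise ValueError("ceiling must be >= threshold")

    @property
    def sigma_iti(self) -> float:
        return self.noise_sd if self.iti_noise_sd is None else self.iti_noise_sd


@dataclass(frozen=True)
class AttractorState:
    """Decision variable and elapsed time; sign of x encodes the option."""

    x: float = 0.0
    t: float = 0.0


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated decision: chosen option, response time, final state."""

    choice: str
    rt: float
    end_state: AttractorState


def potential(x: float, c: float) -> float:
    """Double-well potential ``V(x, c) = x^4/4 - x^2/2 - c x``."""
    return x**4 / 4.0 - x**2 / 2.0 - c * x


def drift(x: float, c: float) -> float:
    """Deterministic force ``-dV/dx = x - x^3 + c``."""
    return x - x * x * x + c


def _clip(x: float, ceiling: float) -> float:
    if x > ceiling:
        return ceiling
    if x < -ceiling:
        return -ceiling
    return x


def step(
    state: AttractorState,
    c: float,
    params: AttractorParams,
    rng: Optional[np.random.Generator] = None,
) -> AttractorState:
    """One Euler–Maruyama step of the within-trial dynamics."""
    eta = 0.0
    if params.noise_sd > 0.0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        eta = rng.standard_normal()
    x = (
        state.x
        + (state.x - state.x * state.x * state.x + c) * (params.dt / params.tau_trial)
        + params.noise_sd * math.sqrt(params.dt) * eta
    )
    return AttractorState(x=_clip(x, params.ceiling), t=state.t + params.dt)


def relax_iti(
    state: AttractorState,
    params: AttractorParams,
    rng: Optional[np.random.Generator] = None,
) -> AttractorState:
    """Integrate the ITI relaxation ``dx = -(x/tau_iti) dt + sigma_iti dW``.

    With ``sigma_iti = 0`` the closed form is ``x(T) = x(0) exp(-T/tau_iti)``,
    which serves as the oracle for the Euler integrator.  The returned state
    generally retains a residual bias toward the previously chosen option.
    """
    sigma = params.sigma_iti
    if sigma > 0.0 and rng is None:
        raise ValueError("rng required when iti noise > 0")
    n_steps = int(round(params.iti_duration / params.dt))
    x = state.x
    sqdt = math.sqrt(params.dt)
    for _ in range(n_steps):
        eta = rng.standard_normal() if sigma > 0.0 else 0.0
        x = x + (-(x / params.tau_iti)) * params.dt + sigma * sqdt * eta
        x = _clip(x, params.ceiling)
    return AttractorState(x=x, t=state.t + n_steps * params.dt)


def run_trial(
    start: AttractorState,
    c: float,
    params: AttractorParams,
    rng: Optional[np.random.Generator] = None,
) -> TrialOutcome:
    """Iterate the within-trial dynamics until a bound crossing or deadline.

    Choice is SN if the crossing is at ``+theta``, LF at ``-theta``; if the
    deadline ``t_max`` passes first the outcome is a TIMEOUT (recorded, never
    dropped).
    """
    if abs(start.x) >= params.threshold:
        raise ValueError(
            f"start state |x|={abs(start.x):.3f} already beyond threshold {params.threshold}"
        )
    n_max = int(round(params.t_max / params.dt))
    state = AttractorState(x=start.x, t=0.0)
    for _ in range(n_max):
        state = step(state, c, params, rng)
        if abs(state.x) >= params.threshold:
            choice = SN if state.x > 0 else LF
            return TrialOutcome(choice=choice, rt=state.t, end_state=state)
    return TrialOutcome(choice=TIMEOUT, rt=math.nan, end_state=state)


def _as_seed(rng: Union[int, np.random.Generator, None]) -> int:
    """Derive a 31-bit integer seed for the compiled kernel."""
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2**31)
    return int(rng.integers(2**31))


def simulate_sequence(
    c_values: Sequence[float],
    params: AttractorParams,
    start: AttractorState = AttractorState(),
    rng: Union[int, np.random.Generator, None] = None,
) -> List[TrialOutcome]:
    """Alternate ITI relaxation and trials over an ordered c schedule.

    The end state of each trial threads through the ITI into the next
    trial's start, which is what produces carryover and hysteresis.  Runs in
    the compiled kernel; noiseless runs agree exactly with composing
    :func:`relax_iti` and :func:`run_trial`.
    """
    c_arr = np.asarray(c_values, dtype=float)
    if c_arr.ndim != 1 or c_arr.size == 0:
        raise ValueError("c_values must be a nonempty 1-d sequence")
    seed = _as_seed(rng)
    codes, rts, end_x = _kernel.simulate_schedule(
        float(start.x),
        c_arr,
        params.dt,
        params.tau_trial,
        params.noise_sd,
        params.threshold,
        params.t_max,
        params.ceiling,
        params.tau_iti,
        params.sigma_iti,
        params.iti_duration,
        seed,
    )
    n_iti = int(round(params.iti_duration / params.dt))
    outcomes = []
    t_base = start.t
    for i in range(c_arr.size):
        t_base += n_iti * params.dt
        rt = float(rts[i])
        t_end = t_base + (rt if math.isfinite(rt) else params.t_max)
        outcomes.append(
            TrialOutcome(
                choice=_CODE_TO_CHOICE[int(codes[i])],
                rt=rt,
                end_state=AttractorState(x=float(end_x[i]), t=t_end),
            )
        )
        t_base = t_end
    return outcomes


def simulate_block(
    trials: pd.DataFrame,
    params: AttractorParams,
    seed: Union[int, np.random.Generator, None],
    m_column: str = "manipulation_point",
    start: AttractorState = AttractorState(),
) -> pd.DataFrame:
    """Simulate choices for a designed trial block (a trial-log frame).

    ``trials`` must carry a manipulation point per trial in ``m_column``;
    it is mapped to the control parameter via the linear gain and the whole
    schedule is run as one carryover-coupled sequence.  Returns a copy of
    the frame with ``choice``, ``rt`` and ``end_x`` columns appended.
    Deterministic given ``seed``.
    """
    out = trials.reset_index(drop=True).copy()
    if len(out) == 0:
        out["choice"] = pd.Series(dtype=object)
        out["rt"] = pd.Series(dtype=float)
        out["end_x"] = pd.Series(dtype=float)
        return out
    m = out[m_column].to_numpy(dtype=float)
    if np.any(~np.isfinite(m)):
        raise ValueError(f"undefined manipulation point in column {m_column!r}")
    c_values = np.array([control_parameter(v, params.control_gain) for v in m])
    outcomes = simulate_sequence(c_values, params, start=start, rng=seed)
    out["choice"] = [o.choice for o in outcomes]
    out["rt"] = [o.rt for o in outcomes]
    out["end_x"] = [o.end_state.x for o in outcomes]
    return out
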