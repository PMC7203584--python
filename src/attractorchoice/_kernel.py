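"""Numba-compiled Euler–Maruyama kernels for the attractor dynamics.

The arithmetic here is deliberately identical, operation for operation, to
the pure-Python reference in :mod:`attractorchoice.attractor` (`step` and
`relax_iti`), so that noiseless runs agree bit-for-bit between the two paths.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# choice codes used by the kernel
CHOICE_SN = 1
CHOICE_LF = -1
CHOICE_TIMEOUT = 0


@njit(cache=True)
def simulate_schedule(
    x0: float,
    c_values: np.ndarray,
    dt: float,
    tau_trial: float,
    sigma: float,
    theta: float,
    t_max: float,
    ceiling: float,
    tau_iti: float,
    sigma_iti: float,
    iti_duration: float,
    seed: int,
):
    """Run a whole c-schedule: (ITI relaxation, then trial) for each c.

    The state threads from the end of one trial through the ITI into the
    next trial.  Returns per-trial choice codes (+1 SN, -1 LF, 0 timeout),
    response times (NaN for timeouts) and the state at decision/deadline.
    """
    np.random.seed(seed)
    n = c_values.shape[0]
    choices = np.empty(n, dtype=np.int64)
    rts = np.empty(n, dtype=np.float64)
    end_x = np.empty(n, dtype=np.float64)

    sqdt = np.sqrt(dt)
    n_iti = int(round(iti_duration / dt))
    n_max = int(round(t_max / dt))
    x = x0

    for i in range(n):
        # inter-trial interval: linear relaxation toward the neutral point
        for _ in range(n_iti):
            x = x + (-(x / tau_iti)) * dt + sigma_iti * sqdt * np.random.normal()
            if x > ceiling:
                x = ceiling
            elif x < -ceiling:
                x = -ceiling
        # within-trial double-well dynamics until threshold crossing
        c = c_values[i]
        choice = CHOICE_TIMEOUT
        rt = np.nan
        for k in range(n_max):
            x = x + (x - x * x * x + c) * (dt / tau_trial) + sigma * sqdt * np.random.normal()
            if x > ceiling:
                x = ceiling
            elif x < -ceiling:
                x = -ceiling
            if x >= theta or x <= -theta:
                choice = CHOICE_SN if x > 0.0 else CHOICE_LF
                rt = (k + 1) * dt
                break
        choices[i] = choice
        rts[i] = rt
        end_x[i] = x
    return choices, rts, end_x
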