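"""Independent reference implementations used as test oracles.

These deliberately avoid the package's adaptive-integration code path:
a fixed-step classical Runge-Kutta stepper with impulse handling, and the
closed-form (Bateman) solution of the two-compartment linear PK system.
"""

import numpy as np


def rk4_reference(fun, t0, t1, y0, h, dose_jumps):
    """Fixed-step RK4 integration segmented at impulse times.

    ``dose_jumps`` maps times to state-increment vectors; every jump time
    is hit exactly.
    """
    boundaries = [t0] + sorted(t for t in dose_jumps if t0 <= t <= t1) + [t1]
    y = np.array(y0, dtype=float)
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if a in dose_jumps:
            y = y + dose_jumps[a]
        n = int(round((b - a) / h))
        hh = (b - a) / n if n else 0.0
        t = a
        for _ in range(n):
            k1 = fun(t, y)
            k2 = fun(t + hh / 2, y + hh / 2 * k1)
            k3 = fun(t + hh / 2, y + hh / 2 * k2)
            k4 = fun(t + hh, y + hh * k3)
            y = y + hh / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += hh
    return y


def bateman_central(t, dose, ka, ke):
    """Closed-form central amount after a single bolus into the depot."""
    t = np.asarray(t, dtype=float)
    return dose * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
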