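"""Inner simulation loop for the spreading-activation models.

Sequentially applies the Rescorla-Wagner update a <- a + r*(1 - a) to every
node on every trial and reads out the raw predicted RT from the pre-update
state. JIT-compiled with numba when available; a pure-Python fallback keeps
the package importable without it.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def run_sequence(
    cond_seq: np.ndarray,  # (T,) int condition indices
    class_idx: np.ndarray,  # (n_conditions, n_nodes) int rate-class ids
    class_rates: np.ndarray,  # (n_classes,) float rates for current params
    readout_idx: np.ndarray,  # (n_conditions, m) int node indices to read
    readout_const: float,  # asymptotic ceiling (2.0, or 1.0 for CAR)
    out: np.ndarray,  # (T,) float raw predicted RTs (written in place)
) -> None:
    n_nodes = class_idx.shape[1]
    m = readout_idx.shape[1]
    a = np.zeros(n_nodes)
    for t in range(cond_seq.shape[0]):
        c = cond_seq[t]
        s = readout_const
        for j in range(m):
            s -= a[readout_idx[c, j]]
        out[t] = s
        for i in range(n_nodes):
            r = class_rates[class_idx[c, i]]
            if r > 0.0:
                a[i] += r * (1.0 - a[i])
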