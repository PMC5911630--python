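"""Independent brute-force oracles, coded separately from the package
implementations they check."""

import numpy as np


def brute_force_logrank(time, event, group):
    """Plain-loop O/E/V accumulation from the hypergeometric moments."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group, bool)
    oe = v = 0.0
    for t in sorted(set(time[event])):
        n = sum(1 for ti in time if ti >= t)
        n1 = sum(1 for ti, gi in zip(time, group) if ti >= t and gi)
        d = sum(1 for ti, ei in zip(time, event) if ti == t and ei)
        d1 = sum(1 for ti, ei, gi in zip(time, event, group) if ti == t and ei and gi)
        oe += d1 - d * n1 / n
        if n > 1:
            v += d * n1 * (n - n1) * (n - d) / (n**2 * (n - 1))
    return oe**2 / v
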