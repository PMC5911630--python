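"""Minimal Kaplan-Meier plot helper."""

from __future__ import annotations

import numpy as np

from .survival import KMCurve


def plot_km(curves: dict[str, KMCurve], ax=None, horizon: float | None = 60.0):
    """Step-plot one KM curve per group label; returns the axes.

    Matplotlib is imported lazily so the library works headless without
    a plotting backend configured.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        if horizon is not None and (t.size == 0 or t[-1] < horizon):
            t = np.append(t, horizon)
            s = np.append(s, s[-1])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
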