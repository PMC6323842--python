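"""Optional matplotlib views of sweep and comparison results."""

from __future__ import annotations

import numpy as np


def plot_sweep(summary, predictor: str, metrics=("delta_d99_pct", "delta_d95_pct"), ax=None):
    """Scatter the worst-case dose deltas against one swept parameter."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    sub = summary.sort_values(predictor)
    for metric in metrics:
        label = metric.replace("delta_d", "ΔD̄").replace("_pct", "")
        ax.plot(sub[predictor], sub[metric], "o-", label=label)
    ax.set_xlabel(predictor)
    ax.set_ylabel("worst-case deviation (%)")
    ax.legend()
    return ax


def plot_paired_d99(comparison, ax=None):
    """Per-fraction Dtrue_99 of the standard vs robust plan."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    fractions = np.arange(1, comparison.standard_pct.size + 1)
    ax.plot(fractions, comparison.standard_pct, "o-", label="standard")
    ax.plot(fractions, comparison.robust_pct, "s-", label="robust")
    ax.set_xlabel("fraction")
    ax.set_ylabel("Dtrue_99 (% of prescription)")
    ax.legend()
    return ax
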