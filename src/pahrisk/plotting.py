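"""Cumulative-probability plots of DI / ILCR simulations."""

from __future__ import annotations

import numpy as np


def plot_cumulative(result, ax=None, label: str | None = None):
    """Empirical cumulative distribution of a simulation's primary samples
    (DI in ng/day or ILCR), with the median and 95th percentile marked."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    x = np.sort(result.samples)
    p = np.arange(1, x.size + 1) / x.size
    st = result.stratum_labels()
    label = label or f"{st['city']} {st['age_group']} {st['gender']}"
    ax.plot(x, p, label=label)
    ax.axhline(0.5, color="grey", lw=0.5, ls=":")
    ax.axhline(0.95, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("daily intake (ng/day)" if result.kind == "di" else "ILCR")
    ax.set_ylabel("cumulative probability")
    if result.kind == "ilcr":
        ax.set_xscale("log")
    ax.legend(fontsize=7)
    return ax
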