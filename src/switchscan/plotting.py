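"""Convenience histogram of one gene's profile with its mixture overlay."""

from __future__ import annotations

import numpy as np

from .mixture import BimodalityResult


def plot_gene_histogram(values, result: BimodalityResult, ax=None, bins: int = 40):
    """Histogram of a profile with the fitted 1- and 2-component densities.

    Requires matplotlib (optional dependency).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if ax is None:
        _, ax = plt.subplots()
    ax.hist(x, bins=bins, density=True, color="0.8", edgecolor="0.5")
    grid = np.linspace(x.min(), x.max(), 400)
    mix = np.exp(result.fit2.component_logpdf(grid)).sum(axis=0)
    single = np.exp(result.fit1.component_logpdf(grid)).sum(axis=0)
    ax.plot(grid, single, "--", label="1 Gaussian")
    ax.plot(grid, mix, "-", label="2-Gaussian mixture")
    ax.set_xlabel("log2 expression")
    ax.set_ylabel("density")
    ax.set_title(f"{result.gene_id}  ΔAIC = {result.delta_aic:.1f}")
    ax.legend()
    return ax
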