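"""Convenience plots: monthly fruiting profiles.

Deliberately minimal — the analysis outputs are the tidy tables; these plots
are quick-look aids, not publication figures.
"""

from __future__ import annotations

import numpy as np

from . import phenology as _ph
from .io import DetectionMatrix

__all__ = ["plot_monthly_profile", "plot_relative_richness"]


def plot_monthly_profile(matrix: DetectionMatrix, group: str, ax=None):
    """Box-style monthly distribution of one group's per-survey counts."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ms = _ph.monthly_samples(matrix, group)
    data = [ms.samples[m] for m in _ph.MONTHS]
    ax.boxplot([d if len(d) else [np.nan] for d in data],
               tick_labels=[str(m) for m in _ph.MONTHS])
    ax.set_xlabel("month")
    ax.set_ylabel("fruiting species")
    ax.set_title(group)
    return ax


def plot_relative_richness(matrix: DetectionMatrix, groups=None, ax=None):
    """Standardized seasonal profiles (one line per group)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g in groups or matrix.groups:
        ax.plot(range(1, 13), _ph.relative_richness(matrix, g), label=g)
    ax.set_xlabel("month")
    ax.set_ylabel("relative richness (z)")
    ax.legend(fontsize="small")
    return ax
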