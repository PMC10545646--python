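"""Summary figures (matplotlib imported lazily; styling is utilitarian)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_sdt_by_noise", "plot_psychometric_functions"]


def plot_sdt_by_noise(estimates: pd.DataFrame, ax_pair=None):
    """Mean A and b (+/- 95% CI over subjects) versus noise level, per modality."""
    import matplotlib.pyplot as plt

    if ax_pair is None:
        _, ax_pair = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, value in zip(ax_pair, ("A", "b")):
        for modality, g in estimates.groupby("modality"):
            by_level = g.groupby("noise_level")[value]
            mean = by_level.mean()
            half = 1.96 * by_level.std(ddof=1) / np.sqrt(by_level.count())
            ax.errorbar(mean.index * 100, mean, yerr=half, marker="o", label=modality)
        ax.set_xlabel("noise level (%)")
        ax.set_ylabel(value)
        ax.legend()
    if value == "b":
        ax.axhline(1.0, color="k", lw=0.5, ls="--")
    return ax_pair


def plot_psychometric_functions(fits, table: pd.DataFrame, target_pc: float = 0.76, ax=None):
    """Group PFs with observed per-gap accuracy and threshold markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    gaps = np.linspace(0.5, 40, 200)
    for fit in fits:
        obs = table[table["modality"] == fit.modality].groupby("gap_ms")["correct"].mean()
        line, = ax.plot(gaps, fit.predict(gaps), label=fit.modality)
        ax.plot(obs.index, obs, "o", color=line.get_color(), ms=4)
        if fit.threshold_ms is not None:
            ax.axvline(fit.threshold_ms, color=line.get_color(), ls=":", lw=0.8)
    ax.axhline(target_pc, color="k", ls="--", lw=0.5)
    ax.set_xlabel("gap duration (ms)")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(0.45, 1.02)
    ax.legend()
    return ax
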