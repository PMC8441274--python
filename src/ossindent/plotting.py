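"""Diagnostic plots for curve reductions and odds-ratio tables.

matplotlib is imported lazily so the analysis stack works headless.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

PHASE_COLORS = {
    "loading": "tab:blue",
    "hold": "tab:orange",
    "unloading": "tab:green",
    "drift_hold": "tab:gray",
}


def plot_indentation(results, ax=None):
    """Force–depth curve coloured by phase, with the unloading fit overlaid.

    Parameters
    ----------
    results : IndentationResults
        A fitted reduction (see :class:`ossindent.IndentationModel`).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    curve = results.curve
    for phase, color in PHASE_COLORS.items():
        m = curve.phase_mask(phase)
        if m.any():
            ax.plot(curve.depth[m], curve.load[m], ".", ms=2, color=color,
                    label=phase)
    f = results.unload_fit
    h_grid = np.linspace(max(f.h_f + 1e-6, 0.0), f.h_max, 200)
    ax.plot(h_grid, f.B * (h_grid - f.h_f) ** f.m, "k--", lw=1,
            label=f"fit m={f.m:.2f}")
    p = results.properties
    h_txt = f"H={p.H:.2f} GPa" if math.isfinite(p.H) else "elastic"
    ax.set_title(f"E={p.E:.1f} GPa, Hc={p.Hc:.2f} GPa, {h_txt}\n"
                 f"Ue={p.Ue:.0f} pJ, Up={p.Up:.0f} pJ", fontsize=9)
    ax.set_xlabel("depth (nm)")
    ax.set_ylabel("load (mN)")
    ax.legend(fontsize=7)
    return ax


def plot_odds_ratios(or_results: Sequence, ax=None):
    """Forest plot of odds ratios with 95% CIs on a log scale."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.5 * len(or_results) + 1.5))
    labels, ors, lows, highs = [], [], [], []
    for r in or_results:
        labels.append(getattr(r, "variable", str(r)))
        ors.append(r.OR)
        lows.append(r.ci_low)
        highs.append(r.ci_high)
    y = np.arange(len(labels))[::-1]
    finite_high = [h if math.isfinite(h) else o * 100 for o, h in zip(ors, highs)]
    ax.hlines(y, lows, finite_high, color="tab:blue")
    ax.plot(ors, y, "s", color="tab:blue")
    ax.axvline(1.0, color="k", lw=0.8, ls=":")
    ax.set_yticks(y, labels)
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio per unit (95% CI)")
    return ax
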