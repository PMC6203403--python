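"""Minimal Manhattan and quantile-quantile plots for association results."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def manhattan(results_table, thresholds=None, ax=None, title: str | None = None):
    """Scatter of -log10 p by marker order, one colour block per chromosome."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    tab = results_table.dropna(subset=["p"]).reset_index(drop=True)
    chroms = [m.split(":")[0] for m in tab.marker]
    neglog = -np.log10(np.maximum(tab.p.values, 1e-300))
    colors = []
    seen = {}
    for c in chroms:
        seen.setdefault(c, len(seen))
        colors.append("#2c7fb8" if seen[c] % 2 == 0 else "#7fcdbb")
    ax.scatter(np.arange(len(tab)), neglog, s=8, c=colors)
    if thresholds is not None:
        ax.axhline(-np.log10(thresholds.bonferroni_p), color="red", lw=0.8, ls="--",
                   label="Bonferroni")
        ax.axhline(-np.log10(thresholds.permutation_p), color="orange", lw=0.8, ls=":",
                   label="permutation")
        ax.legend(fontsize=7)
    ax.set_xlabel("marker index")
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    return ax


def qq(results_table, ax=None, title: str | None = None):
    """Observed versus expected -log10 p under the uniform null."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.2))
    p = np.sort(results_table.p.dropna().values)
    n = len(p)
    if n == 0:
        return ax
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(np.maximum(p, 1e-300))
    ax.scatter(exp, obs, s=8, color="#2c7fb8")
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel("expected")
    ax.set_ylabel("observed")
    if title:
        ax.set_title(title)
    return ax
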