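"""Schematic figure exports (stacked variance bars, conditional-correlation curves)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_varpart(result, path, title="Variance partitioning"):
    """Stacked horizontal bars of per-taxon variance proportions."""
    prop = result.proportions.sort_values("latent")
    fig, ax = plt.subplots(figsize=(8, max(3, 0.18 * len(prop))))
    left = np.zeros(len(prop))
    for g in list(result.groups) + ["latent"]:
        vals = prop[g].to_numpy()
        ax.barh(prop.index, vals, left=left, label=g)
        left += vals
    ax.set_xlabel("proportion of variance")
    ax.set_title(title)
    ax.legend(fontsize=7, loc="lower right")
    ax.tick_params(axis="y", labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_conditional_curve(curve, path, label=""):
    """Conditional correlation along the modifier with bootstrap band."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.grid, curve.rho, marker="o", lw=1.5)
    if np.isfinite(curve.ci_lower).any():
        ax.fill_between(curve.grid, curve.ci_lower, curve.ci_upper, alpha=0.25)
    ax.axhline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("modifier")
    ax.set_ylabel("conditional correlation")
    ax.set_ylim(-1, 1)
    if label:
        ax.set_title(label, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
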