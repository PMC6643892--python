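"""Optional plotting helpers (requires matplotlib).

These are convenience visualizations for LOD profiles, GIC tracks and
haplotypic IBD probabilities; no figure layout is part of the tested API.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_lod_profile(result, ax=None, label=None):
    """Line plot of a QTL scan with its threshold (if set)."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(result.positions, result.lod, label=label)
    if result.threshold is not None:
        ax.axhline(result.threshold, ls="--", color="red", lw=1)
    ax.set_xlabel("position (cM)")
    ax.set_ylabel("LOD")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_gic_track(track, ax=None):
    """Per-homolog GIC lines along the chromosome."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    for j in range(2 * track.ploidy):
        ax.plot(track.positions, track.values[j], label=f"h{j + 1}", lw=1)
    ax.set_xlabel("position (cM)")
    ax.set_ylabel("GIC")
    ax.set_ylim(0, 1.02)
    ax.legend(ncol=2, fontsize=7, frameon=False)
    return ax


def plot_haplotype_probs(hap, individual: int, ax=None):
    """Heat map of per-homolog inheritance probabilities for one offspring."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    img = hap.pi[individual].T  # (2p, L)
    ax.imshow(
        img,
        aspect="auto",
        origin="lower",
        extent=(hap.positions[0], hap.positions[-1], 0.5, 2 * hap.ploidy + 0.5),
        cmap="Blues",
        vmin=0,
        vmax=np.nanmax(img),
    )
    ax.set_xlabel("position (cM)")
    ax.set_ylabel("homolog")
    return ax
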