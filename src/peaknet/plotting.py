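"""Plotting utilities for mutation-effect maps.

The saturation-mutagenesis figure mirrors the field's convention: a
4-row heat map of the predicted accessibility change for every possible
substitution, a reference-sequence track whose nucleotide letters are
drawn with height proportional to the position's loss score (beyond a
minimum height so every base stays legible), and loss/gain line tracks.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .sequence import BASES


def plot_saturation_mutagenesis(result, cell, cell_name=None, path=None,
                                min_letter_height=0.05):
    """Render one cell's mutation map from a :class:`SatMutResult`.

    ``min_letter_height`` is the floor (fraction of the letter axis)
    below which loss-scaled nucleotide letters are not shrunk.
    """
    delta, loss, gain, ref_pred = result.for_cell(cell)
    L = result.length
    fig, axes = plt.subplots(
        3, 1, figsize=(max(8, L / 12), 6), sharex=True,
        gridspec_kw={"height_ratios": [3, 1, 2]},
    )
    vmax = max(1e-6, np.abs(delta).max())
    im = axes[0].imshow(delta.T, aspect="auto", cmap="RdBu_r",
                        vmin=-vmax, vmax=vmax, interpolation="nearest")
    axes[0].set_yticks(range(4), list(BASES))
    axes[0].set_ylabel("mutate to")
    name = cell_name or f"cell {cell}"
    axes[0].set_title(f"{name}: reference prediction {ref_pred:.3f}")
    fig.colorbar(im, ax=axes[0], label="Δ prediction", pad=0.01)

    # reference letters scaled by loss score, floored at min height
    scale = loss / max(loss.max(), 1e-9)
    heights = np.maximum(scale, min_letter_height)
    for p in range(L):
        axes[1].text(p, 0, BASES[result.ref_indices[p]],
                     ha="center", va="bottom", fontsize=9,
                     fontstretch="condensed",
                     transform=axes[1].transData,
                     rotation=0, clip_on=True,
                     fontweight="bold" if scale[p] > 0.5 else "normal",
                     alpha=float(min(1.0, 0.3 + heights[p])))
        axes[1].bar(p, heights[p], width=0.85, color="0.6", alpha=0.35)
    axes[1].set_ylim(0, 1.05)
    axes[1].set_yticks([])
    axes[1].set_ylabel("ref")

    axes[2].plot(np.arange(L), loss, label="loss", color="tab:red", lw=1)
    axes[2].plot(np.arange(L), -gain, label="-gain", color="tab:blue", lw=1)
    axes[2].axhline(0, color="0.3", lw=0.5)
    axes[2].set_xlabel("position (bp)")
    axes[2].set_ylabel("score")
    axes[2].legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def plot_history(history, path=None):
    """Training/validation loss and validation AUC per epoch."""
    fig, ax1 = plt.subplots(figsize=(6, 4))
    epochs = np.arange(history.n_epochs)
    ax1.plot(epochs, history.train_loss, label="train loss")
    ax1.plot(epochs, history.valid_loss, label="valid loss")
    ax1.axvline(history.best_epoch, color="0.5", ls="--", lw=0.8,
                label="best epoch")
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("loss")
    ax2 = ax1.twinx()
    ax2.plot(epochs, history.valid_auc, color="tab:green", label="valid AUC")
    ax2.set_ylabel("mean AUC")
    ax1.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
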