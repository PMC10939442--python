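"""Minimal plotting: the codon x amino-acid landscape as a heatmap."""

from __future__ import annotations

import numpy as np


def landscape_heatmap(landscape, ax=None, log10_floor: float = -6.0):
    """Heatmap of misincorporation probabilities (log10 scale).

    The correct-translation entries dominate every row, so they are masked
    and only error probabilities are shown, floored at ``log10_floor``.
    """
    import matplotlib.pyplot as plt

    from .genetic_code import merge_il, translate

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 14))
    probs = landscape.probs.copy()
    for i, codon in enumerate(landscape.codons):
        aa = translate(codon)
        label = aa if aa in landscape.categories else merge_il(aa)
        probs[i, landscape.categories.index(label)] = np.nan
    with np.errstate(divide="ignore"):
        img = np.log10(np.where(probs > 0, probs, np.nan))
    img = np.maximum(img, log10_floor)
    mesh = ax.imshow(img, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(landscape.categories)))
    ax.set_xticklabels(landscape.categories, rotation=90, fontsize=7)
    ax.set_yticks(range(len(landscape.codons)))
    ax.set_yticklabels(landscape.codons, fontsize=6)
    ax.set_xlabel("misincorporated amino acid")
    ax.set_ylabel("codon")
    ax.figure.colorbar(mesh, ax=ax, label="log10 probability")
    return ax
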