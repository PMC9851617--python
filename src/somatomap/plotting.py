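"""Basic RDM / MDS visualisation helpers (matplotlib, optional)."""

from __future__ import annotations

import numpy as np

from .rsa import RDM, classical_mds

_COLORS = {"forehead": "tab:red", "nose": "gold", "lips": "tab:blue",
           "tongue": "tab:green", "thumb": "tab:gray"}


def plot_rdm(rdm: RDM, ax=None, cmap: str = "viridis"):
    """Heatmap of a condition x condition dissimilarity matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(rdm.d, cmap=cmap)
    ax.set_xticks(range(len(rdm.conditions)), rdm.conditions, rotation=45)
    ax.set_yticks(range(len(rdm.conditions)), rdm.conditions)
    ax.figure.colorbar(im, ax=ax, label="crossnobis distance (a.u.)")
    return ax


def plot_mds(rdm: RDM, ax=None):
    """2-D classical-MDS projection of an RDM, one marker per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    coords = classical_mds(rdm, k=2)
    for cond, (x, y) in zip(rdm.conditions, coords):
        ax.scatter(x, y, color=_COLORS.get(cond, "k"), label=cond, s=60)
        ax.annotate(cond, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("MDS dim 1")
    ax.set_ylabel("MDS dim 2")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    return ax
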