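"""Basic diagnostic plots: per-SNP effects and window variances."""

from __future__ import annotations

import numpy as np

from .qtlmap import WindowVarianceTable
from .syndata import MarkerMap


def plot_snp_effects(effects, marker_map: MarkerMap, ax=None, abs_values=True):
    """Manhattan-style plot of |effect| per SNP, colored by chromosome."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    e = np.abs(effects) if abs_values else np.asarray(effects)
    for c in marker_map.chromosomes:
        idx = marker_map.snps_on(c)
        ax.scatter(idx, e[idx], s=4, label=f"chr{c}")
    ax.set_xlabel("SNP index")
    ax.set_ylabel("|effect|" if abs_values else "effect")
    ax.legend(fontsize=7, ncol=5)
    return ax


def plot_window_variances(table: WindowVarianceTable, ax=None):
    """Window variance proportion against window start SNP."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    w = table.windows
    for c in sorted(w["chrom"].unique()):
        sub = w[w["chrom"] == c]
        ax.plot(sub["first_snp"], sub["proportion"], lw=0.8, label=f"chr{c}")
    ax.set_xlabel("window start SNP")
    ax.set_ylabel("proportion of GEBV variance")
    ax.legend(fontsize=7, ncol=5)
    return ax
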