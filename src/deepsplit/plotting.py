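"""Optional matplotlib renderings of the census and pathway tables."""

from __future__ import annotations

import pandas as pd


def plot_motif_census(census: pd.DataFrame, ax=None):
    """Bar chart of per-genome general-motif proportions (one bar per genome)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.12 * len(census)), 3))
    ax.bar(range(len(census)), census["proportion_general"], width=0.9)
    ax.set_xticks(range(len(census)))
    ax.set_xticklabels(census["genome_id"], rotation=90, fontsize=5)
    ax.set_ylabel("proportion of proteins\nwith the general motif")
    return ax


def plot_taxon_pathway_heatmap(taxon_matrix: pd.DataFrame, ax=None):
    """Heatmap of per-taxon pathway presence proportions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(1 + 0.6 * taxon_matrix.shape[1],
                     1 + 0.25 * taxon_matrix.shape[0]))
    im = ax.imshow(taxon_matrix.to_numpy(), vmin=0, vmax=1, aspect="auto",
                   cmap="viridis")
    ax.set_xticks(range(taxon_matrix.shape[1]))
    ax.set_xticklabels(taxon_matrix.columns, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(taxon_matrix.shape[0]))
    ax.set_yticklabels(taxon_matrix.index, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="proportion of genomes present")
    return ax
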