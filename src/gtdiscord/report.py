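"""Summary outputs: discordance distribution, heatmap, allele-fraction plots.

Every plot also dumps its underlying numbers as TSV next to the image so the
outputs are testable (and grep-able) without touching pixels.  Images are
written in both a raster (PNG) and a vector (SVG) format.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .comparison import DiscordanceMatrix
from .errors import EmptyReportError, UnknownSampleError
from .vcf_io import AlleleFractionTable

logger = logging.getLogger(__name__)

_FORMATS = ("png", "svg")


def _save(fig, out_prefix: Path, dpi: int) -> list[Path]:
    paths = []
    for fmt in _FORMATS:
        p = out_prefix.with_suffix(f".{fmt}")
        fig.savefig(p, dpi=dpi, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def plot_discordance_distribution(
    matrix: DiscordanceMatrix,
    out_prefix: str | Path,
    zoom_max: float | None = None,
    bin_width: float = 0.01,
    dpi: int = 150,
) -> list[Path]:
    """Histogram of all defined pair discordance rates.

    With ``zoom_max`` set, a second panel truncates the *count* axis to
    expose the low-discordance same-individual mode that is otherwise dwarfed
    by the unrelated-pair mass.  Bin width defaults to one percentage point.
    Writes ``<prefix>.png/.svg`` and ``<prefix>.tsv`` (bin_left, bin_right,
    count).
    """
    out_prefix = Path(out_prefix)
    rates = matrix.defined_rates()
    if rates.size == 0:
        raise EmptyReportError("no defined pair discordance rates to plot")
    edges = np.arange(0, 1 + bin_width, bin_width)
    counts, edges = np.histogram(rates, bins=edges)
    pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    ).to_csv(out_prefix.with_suffix(".tsv"), sep="\t", index=False)

    ncols = 2 if zoom_max is not None else 1
    fig, axes = plt.subplots(1, ncols, figsize=(6 * ncols, 4), squeeze=False)
    for ax in axes[0]:
        ax.bar(edges[:-1], counts, width=bin_width, align="edge", color="#3b6ea5")
        ax.set_xlabel("discordance rate")
        ax.set_ylabel("sample pairs")
    axes[0][0].set_title(f"Pairwise discordance ({rates.size} pairs)")
    if zoom_max is not None:
        # zoom_max is a fraction of the tallest bar: 0.05 keeps 5% of the peak
        axes[0][1].set_ylim(0, max(1.0, zoom_max * counts.max()))
        axes[0][1].set_title("zoomed count axis")
    return _save(fig, out_prefix, dpi)


def plot_discordance_heatmap(
    matrix: DiscordanceMatrix, out_prefix: str | Path, dpi: int = 150
) -> list[Path]:
    """Sample-by-sample heatmap in manifest order (no clustering).

    Low discordance maps to the dark-red end of the scale so same-individual
    blocks stand out; undefined cells are drawn in grey.  When samples are
    grouped by individual in the manifest, matching samples appear as dark
    cells hugging the diagonal.  The plotted matrix is also written as
    ``<prefix>.tsv``.
    """
    out_prefix = Path(out_prefix)
    df = pd.DataFrame(
        matrix.rates, index=matrix.sample_names, columns=matrix.sample_names
    )
    df.to_csv(out_prefix.with_suffix(".tsv"), sep="\t", na_rep="NA")
    n = matrix.n_samples
    fig, ax = plt.subplots(figsize=(max(4, n * 0.25), max(3.5, n * 0.22)))
    cmap = matplotlib.colormaps["Reds_r"].copy()
    cmap.set_bad("#bbbbbb")
    sns.heatmap(
        df,
        ax=ax,
        cmap=cmap,
        vmin=0,
        vmax=max(0.6, float(np.nanmax(matrix.rates))),
        square=True,
        cbar_kws={"label": "discordance rate"},
        xticklabels=n <= 40,
        yticklabels=n <= 40,
    )
    ax.set_title("Pairwise genotype discordance (input order)")
    return _save(fig, out_prefix, dpi)


def plot_allele_fractions(
    table: AlleleFractionTable,
    sample: str,
    out_prefix: str | Path,
    dpi: int = 150,
) -> list[Path]:
    """Variant-read fraction vs genomic order for one sample, colored by
    chromosome; y axis fixed to [0, 1].

    A clean diploid sample bands near 0, 0.5 and 1; intermediate bands
    suggest contamination or copy-number change.  Data dumped to
    ``<prefix>.tsv``.
    """
    out_prefix = Path(out_prefix)
    sub = table.for_sample(sample)
    if len(sub) == 0:
        raise UnknownSampleError(f"no allele-fraction data for sample {sample!r}")
    sub = sub.sort_values(["chrom", "pos"]).reset_index(drop=True)
    sub.to_csv(out_prefix.with_suffix(".tsv"), sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(8, 3.5))
    palette = sns.color_palette("husl", sub["chrom"].nunique())
    for color, (chrom, grp) in zip(palette, sub.groupby("chrom", sort=True)):
        ax.scatter(grp.index, grp["fraction"], s=4, color=color, label=chrom)
    ax.set_ylim(0, 1)
    ax.set_xlabel("panel position (genomic order)")
    ax.set_ylabel("variant read fraction")
    ax.set_title(f"Allele fractions: {sample}")
    ax.legend(markerscale=3, fontsize=8, loc="center left", bbox_to_anchor=(1, 0.5))
    return _save(fig, out_prefix, dpi)
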