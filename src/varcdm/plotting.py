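"""Static rendering of profiler outputs (cosmetic layer).

The figures mirror the conventional mutation-landscape displays: a
waterfall (patient-by-gene) panel with a per-gene frequency bar, and a
stacked variant-type bar.  Nothing here is contract-bearing; the
underlying tables come from :mod:`varcdm.profiler`.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Patch

from .profiler import WATERFALL_PRIORITY, WaterfallMatrix

#: one colour per variant_feature class, most deleterious first
FEATURE_COLORS = {
    "nonsense": "#d62728",
    "frameshift": "#ff7f0e",
    "splice": "#9467bd",
    "inframe": "#8c564b",
    "missense": "#1f77b4",
    "synonymous": "#2ca02c",
    "intron": "#bcbd22",
    "other": "#7f7f7f",
}


def plot_waterfall(matrix: WaterfallMatrix, path: str | Path,
                   title: str = "") -> Path:
    """Render a waterfall matrix to ``path`` (PNG/SVG by extension)."""
    n_genes, n_patients = len(matrix.genes), len(matrix.patients)
    fig, (ax_bar, ax_grid) = plt.subplots(
        1, 2, figsize=(max(6.0, 0.06 * n_patients + 2.5), 0.45 * n_genes + 1.8),
        gridspec_kw={"width_ratios": [1, 6]}, sharey=True,
    )
    for gi, gene in enumerate(matrix.genes):
        y = n_genes - 1 - gi
        ax_bar.barh(y, matrix.gene_frequencies[gene], color="#555555")
        for pi, patient in enumerate(matrix.patients):
            feature = matrix.cell(gene, patient)
            if feature is None:
                continue
            ax_grid.add_patch(plt.Rectangle(
                (pi, y - 0.4), 1, 0.8,
                color=FEATURE_COLORS.get(feature, "#7f7f7f"), linewidth=0,
            ))
    ax_bar.set_yticks(range(n_genes))
    ax_bar.set_yticklabels(list(reversed(matrix.genes)), fontsize=8)
    ax_bar.set_xlabel("variant frequency")
    ax_bar.invert_xaxis()
    ax_grid.set_xlim(0, n_patients)
    ax_grid.set_ylim(-0.6, n_genes - 0.4)
    ax_grid.set_xlabel(f"patients (n={n_patients})")
    ax_grid.set_xticks([])
    handles = [Patch(color=FEATURE_COLORS[f], label=f)
               for f in WATERFALL_PRIORITY]
    ax_grid.legend(handles=handles, loc="upper right", fontsize=7,
                   framealpha=0.9)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_variant_type_bars(proportions: dict[str, list[tuple[str, int, float]]],
                           path: str | Path, title: str = "") -> Path:
    """Side-by-side variant-type proportion bars, one group per site.

    ``proportions`` maps site label -> output of
    :func:`varcdm.profiler.variant_type_proportions`.
    """
    sites = list(proportions)
    types = [t for t, _c, _p in proportions[sites[0]]]
    fig, ax = plt.subplots(figsize=(1.2 * len(types) + 2, 3.5))
    width = 0.8 / len(sites)
    for si, site in enumerate(sites):
        values = {t: p for t, _c, p in proportions[site]}
        xs = [i + si * width for i in range(len(types))]
        ax.bar(xs, [values.get(t, 0.0) for t in types], width=width,
               label=site)
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(types))])
    ax.set_xticklabels(types, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("proportion of variant rows")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
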