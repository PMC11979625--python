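"""Diagnostic figures: conditional Q-Q curves and a conjFDR Manhattan plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datatypes import QqCurves, SharedLocus


def plot_conditional_qq(curves: QqCurves, ax=None, title: str = "Conditional Q-Q"):
    """Observed vs expected -log10 p of trait 1, one curve per trait-2 stratum.

    Progressive leftward deflection with stricter strata indicates
    cross-trait polygenic enrichment.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for s in curves.strata:
        label = f"p2 <= {s.threshold:g} (n={s.n})"
        if s.low_count:
            label += " [low count]"
        ax.plot(s.expected, s.observed, label=label, lw=1.2)
    lim = max((s.expected.max() for s in curves.strata if s.n), default=1.0)
    ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="null")
    ax.set_xlabel("expected -log10 p (trait 1)")
    ax.set_ylabel("observed -log10 p (trait 1)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def plot_manhattan(
    conj: pd.Series,
    panel: pd.DataFrame,
    loci: list[SharedLocus],
    threshold: float = 0.01,
    ax=None,
):
    """-log10 conjFDR by genomic position, lead SNPs circled."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.5))
    tbl = panel.set_index("snp").loc[conj.index]
    y = -np.log10(np.maximum(conj.to_numpy(float), 1e-300))
    offset = 0.0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(tbl.groupby("chrom", sort=True)):
        x = grp["pos"].to_numpy(float) + offset - grp["pos"].min()
        sel = tbl["chrom"] == chrom
        ax.scatter(x, y[sel.to_numpy()], s=4, color=f"C{i % 2}", rasterized=True)
        ticks.append(offset + (x.max() - x.min()) / 2)
        labels.append(str(chrom))
        pos_map = dict(zip(grp.index, x))
        for locus in loci:
            if locus.chrom == chrom and locus.lead_snp in pos_map:
                ax.scatter(
                    pos_map[locus.lead_snp],
                    -np.log10(max(locus.lead_conjfdr, 1e-300)),
                    s=60, facecolors="none", edgecolors="black", zorder=3,
                )
        offset += x.max() - x.min() + 1e6
    ax.axhline(-np.log10(threshold), color="grey", ls=":", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 conjFDR")
    return ax
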