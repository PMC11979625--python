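"""Conditional/conjunctional FDR analysis of two GWAS summary tables.

The conditional FDR of trait 1 given trait 2 is the empirical-Bayes quantity

    condFDR(p1 | p2) = p1 * W(p2) / W(p1, p2)

where W(p2) is the (LD-pruning-weighted) number of variants whose trait-2
p-value passes p2 and W(p1, p2) additionally requires the trait-1 p-value to
pass p1: conditioning on association with the second trait reranks variants
for the first. The conjunctional FDR is the maximum of the two reciprocal
conditional FDRs, a conservative posterior bound on a variant being null for
either trait. Variants passing the conjFDR threshold are clumped into loci
by LD, each represented by its minimum-conjFDR lead SNP, and leads are
mapped to genes by interval containment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .datatypes import FdrLookup, GwasSummary, LdReference, QqCurves, QqStratum, SharedLocus

_LOW_COUNT = 100
_NODE_SNAP = 1e-9


def _merge(gwas1: GwasSummary, gwas2: GwasSummary) -> pd.DataFrame:
    t1 = gwas1.table[["snp", "p"]].rename(columns={"p": "p1"})
    t2 = gwas2.table[["snp", "p"]].rename(columns={"p": "p2"})
    merged = t1.merge(t2, on="snp", how="inner")
    if merged.empty:
        raise ValueError("no shared variant ids between the two GWAS tables")
    return merged


def conditional_qq(
    gwas1: GwasSummary,
    gwas2: GwasSummary,
    strata: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001),
) -> QqCurves:
    """Trait-1 Q-Q curves within nested strata of trait-2 significance.

    For stratum threshold s the curve uses trait-1 p-values of variants with
    trait-2 p <= s; the expected quantile of rank i among n is
    -log10(i / (n + 1)). Leftward deflection that strengthens with stricter
    strata is the signature of cross-trait enrichment.
    """
    strata = tuple(strata)
    if not strata or strata[0] != 1.0:
        raise ValueError("strata must start at 1.0")
    if any(not (0 < s <= 1) for s in strata):
        raise ValueError("strata thresholds must lie in (0, 1]")
    if any(b >= a for a, b in zip(strata, strata[1:])):
        raise ValueError("strata must be sorted in descending order")
    merged = _merge(gwas1, gwas2)
    out = []
    for s in strata:
        p1 = np.sort(merged.loc[merged["p2"] <= s, "p1"].to_numpy())[::-1]
        n = len(p1)
        ranks = np.arange(n, 0, -1)  # rank of each sorted-descending p-value
        expected = -np.log10(ranks / (n + 1.0))
        observed = -np.log10(p1)
        out.append(QqStratum(s, n, expected, observed, low_count=n < _LOW_COUNT))
    return QqCurves(out)


def random_prune(
    ld: LdReference, r2_max: float = 0.1, n_iter: int = 100, seed: int = 0
) -> pd.Series:
    """Per-variant inclusion weights from repeated random LD pruning.

    Each iteration keeps a random maximal subset with all pairwise r-squared
    <= r2_max (greedy over a random priority order, per block); the weight is
    each variant's inclusion fraction. Down-weighting variants in strong LD
    keeps the lookup's empirical cdfs from being dominated by large LD blocks.
    """
    if not (0 < r2_max <= 1):
        raise ValueError(f"r2_max must lie in (0, 1], got {r2_max}")
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(seed)
    panel = ld.panel.table
    counts = np.zeros(len(panel))
    start = 0
    for R in ld.blocks:
        m = len(R)
        conflict = (R**2 > r2_max) & ~np.eye(m, dtype=bool)
        if not conflict.any():
            counts[start : start + m] = n_iter
        else:
            block_counts = np.zeros(m)
            for _ in range(n_iter):
                order = rng.permutation(m)
                blocked = np.zeros(m, dtype=bool)
                for v in order:
                    if not blocked[v]:
                        block_counts[v] += 1
                        blocked |= conflict[v]
                        blocked[v] = True  # keep v itself eligible only once
            counts[start : start + m] = block_counts
        start += m
    return pd.Series(counts / n_iter, index=panel["snp"].to_numpy())


def _snap(coords: np.ndarray, step: float) -> np.ndarray:
    """Round coordinates within 1e-9 of a grid node onto the node."""
    nearest = np.round(coords / step) * step
    return np.where(np.abs(coords - nearest) < _NODE_SNAP, nearest, coords)


def build_condfdr_lookup(
    gwas1: GwasSummary,
    gwas2: GwasSummary,
    weights: pd.Series | None = None,
    grid_max: float = 10.0,
    grid_n: int = 101,
) -> FdrLookup:
    """Binned empirical condFDR(p1 | p2) over a -log10 p grid.

    Node (i, j) holds min(1, t1 * W(t2) / W(t1, t2)) at thresholds
    t = 10**-x; empty cells take the cap value 1; each p2 row is then made
    nonincreasing along -log10 p1 by a cumulative minimum (the raw counting
    estimator is nonmonotone under sparsity). Values beyond the grid edge
    fall into overflow bins, i.e. are counted at the edge node.
    """
    merged = _merge(gwas1, gwas2)
    if weights is None:
        w = np.ones(len(merged))
        n_iter = 0
    else:
        w = weights.loc[merged["snp"]].to_numpy(float)
        n_iter = -1
    x = np.linspace(0.0, grid_max, grid_n)
    step = x[1] - x[0]
    # snap coordinates within float noise of a node onto it, so that a
    # variant with p exactly at a node threshold is counted as passing it
    # (-log10 can land an ulp on either side of the node)
    x1 = _snap(-np.log10(merged["p1"].to_numpy()), step)
    x2 = _snap(-np.log10(merged["p2"].to_numpy()), step)
    edges = np.append(x, np.inf)
    H, _, _ = np.histogram2d(x1, x2, bins=(edges, edges), weights=w)
    # W12[i, j] = total weight with -log10 p1 >= x[i] and -log10 p2 >= x[j]
    W12 = np.cumsum(np.cumsum(H[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]
    W2 = W12[0, :]  # p1 <= 1 always holds
    t1 = 10.0 ** -x
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = t1[:, None] * W2[None, :] / W12
    vals[W12 == 0] = 1.0
    vals = np.minimum(vals, 1.0)
    vals = np.minimum.accumulate(vals, axis=0)
    return FdrLookup(x=x, values=vals, n_prune_iter=n_iter, weights=w)


def assign_condfdr(
    gwas1: GwasSummary, gwas2: GwasSummary, lookup: FdrLookup
) -> pd.Series:
    """Per-variant condFDR of trait 1 given trait 2 from the lookup table.

    Bilinear interpolation in (-log10 p1, -log10 p2); coordinates within
    1e-9 of a grid node snap to the node, and coordinates beyond the grid
    edge clamp to it.
    """
    merged = _merge(gwas1, gwas2)
    for col in ("p1", "p2"):
        p = merged[col].to_numpy()
        if np.any((p <= 0) | (p > 1)):
            raise ValueError(f"{col} outside (0, 1]")
    x = lookup.x
    step = x[1] - x[0]

    def coord(p):
        return np.clip(_snap(-np.log10(p), step), x[0], x[-1])

    interp = RegularGridInterpolator((x, x), lookup.values, method="linear")
    pts = np.column_stack([coord(merged["p1"].to_numpy()), coord(merged["p2"].to_numpy())])
    vals = interp(pts)
    return pd.Series(np.clip(vals, 0.0, 1.0), index=merged["snp"].to_numpy())


def conjfdr(cond12: pd.Series, cond21: pd.Series) -> pd.Series:
    """Conjunctional FDR: the per-variant maximum of the two condFDRs."""
    if set(cond12.index) != set(cond21.index):
        raise ValueError("the two condFDR series cover different variant sets")
    cond21 = cond21.loc[cond12.index]
    return np.maximum(cond12, cond21)


def define_loci(
    conj: pd.Series,
    ld: LdReference,
    gwas1: GwasSummary,
    gwas2: GwasSummary,
    threshold: float = 0.01,
    r2_clump: float = 0.1,
) -> list[SharedLocus]:
    """Greedy LD clumping of conjFDR-passing variants into shared loci.

    Passing variants are visited in ascending conjFDR (ties broken by the
    smaller trait-1 p, then variant id); each unassigned variant seeds a new
    locus and absorbs every unassigned passing variant with r-squared >=
    r2_clump to it. The seed is the locus lead. An empty passing set yields
    an empty list.
    """
    if not (0 < r2_clump < 1):
        raise ValueError(f"r2_clump must lie in (0, 1), got {r2_clump}")
    passing = conj[conj < threshold]
    if passing.empty:
        return []
    p1 = gwas1.indexed("p")
    z1 = gwas1.indexed("z")
    z2 = gwas2.indexed("z")
    panel = ld.panel.table.set_index("snp")
    order = sorted(passing.index, key=lambda s: (passing[s], p1[s], s))

    rows = ld.panel.rows_of(order)
    block = ld.block_of(rows)
    R = {b: ld.blocks[b] for b in np.unique(block)}
    offset = dict(zip(order, (int(o) for o in ld.offset_of(rows))))

    assigned: set[str] = set()
    loci: list[SharedLocus] = []
    for k, sid in enumerate(order):
        if sid in assigned:
            continue
        b = block[k]
        members = [sid]
        for j in range(k + 1, len(order)):
            other = order[j]
            if other in assigned or block[j] != b:
                continue
            r = R[b][offset[sid], offset[other]]
            if r * r >= r2_clump:
                members.append(other)
        assigned.update(members)
        loci.append(
            SharedLocus(
                index=len(loci) + 1,
                members=members,
                lead_snp=sid,
                lead_conjfdr=float(passing[sid]),
                chrom=panel.at[sid, "chrom"],
                pos=int(panel.at[sid, "pos"]),
                z1=float(z1[sid]),
                z2=float(z2[sid]),
            )
        )
    return loci


def map_genes(
    loci: list[SharedLocus], annotation: pd.DataFrame, flank: int = 0
) -> list[SharedLocus]:
    """Attach the genes whose interval (+- flank) contains each lead SNP.

    ``annotation`` uses 1-based inclusive coordinates (columns gene, chrom,
    start, end). A lead outside every interval gets an empty list, reported
    downstream as intergenic.
    """
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    if (annotation["start"] > annotation["end"]).any():
        raise ValueError("annotation has intervals with start > end")
    for locus in loci:
        hit = annotation[
            (annotation["chrom"] == locus.chrom)
            & (annotation["start"] - flank <= locus.pos)
            & (annotation["end"] + flank >= locus.pos)
        ]
        locus.mapped_genes = hit["gene"].tolist()
    return loci


def concordance_check(
    loci: list[SharedLocus], gwas1: GwasSummary, gwas2: GwasSummary
) -> list[SharedLocus]:
    """Flag each locus lead as direction-concordant across the two traits.

    A zero z-score has sign 0 and is flagged discordant (with a warning note
    attached to the locus via ``concordant = False``).
    """
    z1 = gwas1.indexed("z")
    z2 = gwas2.indexed("z")
    for locus in loci:
        s1 = np.sign(z1[locus.lead_snp])
        s2 = np.sign(z2[locus.lead_snp])
        locus.concordant = bool(s1 == s2 and s1 != 0)
    return loci


def loci_table(loci: list[SharedLocus]) -> pd.DataFrame:
    """Flat per-locus table (lead SNP, position, genes, conjFDR, z1, z2)."""
    return pd.DataFrame(
        [
            {
                "locus": l.index,
                "lead_snp": l.lead_snp,
                "chrom": l.chrom,
                "pos": l.pos,
                "genes": ",".join(l.mapped_genes) if l.mapped_genes else "intergenic",
                "conjfdr": l.lead_conjfdr,
                "z1": l.z1,
                "z2": l.z2,
                "n_members": len(l.members),
                "concordant": l.concordant,
            }
            for l in loci
        ]
    )
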