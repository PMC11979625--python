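"""Core in-memory containers shared across the pipeline stages.

Everything is a light wrapper around a :class:`pandas.DataFrame` or a list of
:class:`numpy.ndarray`, with the statistical invariants of the pipeline
(p/z consistency, unit-diagonal correlation blocks, disjoint loci, ...)
enforced at construction so downstream code can rely on them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Smallest p-value ever reported; avoids underflow to 0, which would break
#: log-scale binning in the condFDR lookup.
P_FLOOR = 1e-300

PANEL_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "maf", "block"]
GWAS_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "z", "p", "n"]

#: Strand-ambiguous allele pairs (indistinguishable from their reverse
#: complement without strand metadata).
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def two_sided_p(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided standard-normal tail probability of ``z``, floored at 1e-300."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, P_FLOOR, 1.0)


class VariantPanel:
    """Reference variant panel: one row per variant, grouped into LD blocks.

    Positions are 1-based and strictly increasing within a chromosome;
    variant ids are unique; 0 < maf <= 0.5.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in PANEL_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"variant panel missing columns: {missing}")
        table = table.reset_index(drop=True)
        if table["snp"].duplicated().any():
            dups = table.loc[table["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate variant ids in panel: {dups[:5]}")
        maf = table["maf"].to_numpy(float)
        if np.any((maf <= 0) | (maf > 0.5)):
            raise ValueError("panel maf values must lie in (0, 0.5]")
        for chrom, grp in table.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        self.table = table
        self._row_of = pd.Series(table.index.to_numpy(), index=table["snp"])

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Series:
        return self.table["snp"]

    def rows_of(self, ids: Sequence[str]) -> np.ndarray:
        """Panel row indices of the given variant ids (raises on unknown id)."""
        try:
            return self._row_of.loc[list(ids)].to_numpy()
        except KeyError as exc:
            raise KeyError(f"variant id not in panel: {exc}") from exc


class LdReference:
    """Variant panel plus one correlation matrix per LD block.

    Blocks are mutually independent: cross-block correlation is exactly zero
    by construction, so any multi-block submatrix is block diagonal.
    """

    def __init__(self, panel: VariantPanel, blocks: Sequence[np.ndarray]):
        block_ids = panel.table["block"].to_numpy()
        n_blocks = int(block_ids.max()) + 1 if len(block_ids) else 0
        if len(blocks) != n_blocks:
            raise ValueError(
                f"panel references {n_blocks} blocks but {len(blocks)} matrices given"
            )
        sizes = np.bincount(block_ids, minlength=n_blocks)
        for b, R in enumerate(blocks):
            R = np.asarray(R, float)
            if R.shape != (sizes[b], sizes[b]):
                raise ValueError(f"block {b}: matrix shape {R.shape} != size {sizes[b]}")
            if not np.allclose(R, R.T, atol=1e-12):
                raise ValueError(f"block {b}: correlation matrix not symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-12):
                raise ValueError(f"block {b}: diagonal not 1")
            if np.any(np.abs(R) > 1 + 1e-12):
                raise ValueError(f"block {b}: entries outside [-1, 1]")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise ValueError(f"block {b}: matrix not positive semi-definite")
        self.panel = panel
        self.blocks = [np.asarray(R, float) for R in blocks]
        # per-variant (block, offset-within-block)
        self._block = block_ids
        self._offset = np.concatenate(
            [np.arange(s) for s in sizes]
        ) if len(block_ids) else np.array([], int)
        self._chol_cache: dict[int, np.ndarray] = {}

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, rows: np.ndarray) -> np.ndarray:
        return self._block[rows]

    def offset_of(self, rows: np.ndarray) -> np.ndarray:
        """Within-block offsets of the given panel rows."""
        return self._offset[rows]

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        """Correlation matrix of the given variants in the given order.

        Cross-block entries are zero.
        """
        rows = self.panel.rows_of(ids)
        b = self._block[rows]
        off = self._offset[rows]
        m = len(rows)
        R = np.zeros((m, m))
        for blk in np.unique(b):
            sel = np.where(b == blk)[0]
            R[np.ix_(sel, sel)] = self.blocks[blk][np.ix_(off[sel], off[sel])]
        return R

    def cholesky(self, block: int) -> np.ndarray:
        """Lower Cholesky factor of a block matrix (jittered, cached)."""
        L = self._chol_cache.get(block)
        if L is None:
            R = self.blocks[block]
            L = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
            self._chol_cache[block] = L
        return L


class GwasSummary:
    """Per-variant association summary for one trait.

    The stored p-value always equals the two-sided normal tail of z (checked
    to 1e-10 relative tolerance at construction; pass ``p=None`` to derive it).
    """

    def __init__(self, table: pd.DataFrame):
        required = ["snp", "a1", "z", "p", "n"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"GWAS summary missing columns: {missing}")
        table = table.reset_index(drop=True)
        if table["snp"].duplicated().any():
            dups = table.loc[table["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate variant ids in GWAS summary: {dups[:5]}")
        z = table["z"].to_numpy(float)
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite z-scores in GWAS summary")
        p = table["p"].to_numpy(float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        expect = two_sided_p(z)
        rel = np.abs(p - expect) / np.maximum(expect, P_FLOOR)
        if np.any(rel > 1e-10):
            bad = table["snp"].to_numpy()[rel > 1e-10][:5].tolist()
            raise ValueError(
                f"p inconsistent with z beyond 1e-10 relative tolerance at {bad}"
            )
        self.table = table

    @classmethod
    def from_z(cls, table: pd.DataFrame) -> "GwasSummary":
        """Build a summary from a table with z but no (or stale) p column."""
        table = table.copy()
        table["p"] = two_sided_p(table["z"].to_numpy(float))
        return cls(table)

    def __len__(self) -> int:
        return len(self.table)

    def indexed(self, column: str) -> pd.Series:
        return pd.Series(self.table[column].to_numpy(), index=self.table["snp"])


class ExpressionMatrix:
    """Genes x samples abundance matrix with a group label per sample."""

    def __init__(self, values: pd.DataFrame, groups: pd.Series):
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not values.columns.equals(pd.Index(groups.index)):
            raise ValueError("group labels do not match sample columns")
        counts = groups.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"groups with fewer than 2 samples: {small}")
        self.values = values
        self.groups = groups

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def group_values(self, gene: str, group: str) -> np.ndarray:
        if gene not in self.values.index:
            raise KeyError(f"gene not in expression matrix: {gene}")
        if group not in set(self.groups):
            raise KeyError(f"unknown group label: {group}")
        cols = self.groups.index[self.groups == group]
        return self.values.loc[gene, cols].to_numpy(float)


@dataclass
class ProteinWeightModel:
    """Cis-SNP weight vectors for one protein, one vector per model family."""

    gene: str
    chrom: object
    cis_start: int
    cis_end: int
    snp_ids: list[str]
    a1: list[str]
    a2: list[str]
    weights: dict[str, np.ndarray]
    cv_r2: dict[str, float]
    best_model: str | None
    dropped_snps: list[str] = field(default_factory=list)
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.degenerate:
            if self.best_model is None:
                raise ValueError("non-degenerate model requires a best_model")
            eligible = {
                m for m, w in self.weights.items() if np.any(np.asarray(w) != 0)
            }
            if not eligible:
                raise ValueError("at least one model must have nonzero weights")
            best_of_eligible = max(eligible, key=lambda m: self.cv_r2[m])
            if not np.isclose(self.cv_r2[self.best_model], self.cv_r2[best_of_eligible]):
                raise ValueError("best_model is not the cv_r2 argmax")
            if "top1" in self.weights:
                if np.count_nonzero(self.weights["top1"]) != 1:
                    raise ValueError("top1 must have exactly one nonzero weight")


@dataclass
class PwasResult:
    """One gene's PWAS association with one trait."""

    gene: str
    z_pwas: float
    p: float
    significant: bool = False
    model_used: str | None = None
    n_snps_used: int = 0
    skipped: bool = False
    skip_reason: str | None = None

    def __post_init__(self):
        if not self.skipped:
            expect = float(two_sided_p(self.z_pwas))
            if abs(self.p - expect) / max(expect, P_FLOOR) > 1e-10:
                raise ValueError(
                    f"{self.gene}: p={self.p} inconsistent with z={self.z_pwas}"
                )


@dataclass
class QqStratum:
    threshold: float
    n: int
    expected: np.ndarray
    observed: np.ndarray
    low_count: bool


@dataclass
class QqCurves:
    """Conditional Q-Q curves: trait-1 quantiles within trait-2 p strata."""

    strata: list[QqStratum]

    def __post_init__(self):
        counts = [s.n for s in self.strata]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("stratum SNP counts must be nonincreasing")
        for s in self.strata:
            if np.any(s.observed < 0) or np.any(np.diff(s.observed) < 0):
                raise ValueError("observed quantiles must be nonnegative, nondecreasing")

    def mean_shift(self) -> dict[float, float]:
        """Mean leftward deflection (observed - expected) per stratum."""
        return {
            s.threshold: float(np.mean(s.observed - s.expected)) if s.n else np.nan
            for s in self.strata
        }


@dataclass
class FdrLookup:
    """Binned empirical condFDR(p1 | p2) lookup on a -log10 p grid.

    ``values[i, j]`` is the condFDR at thresholds p1 = 10**-x[i],
    p2 = 10**-x[j]; rows are nonincreasing along increasing -log10 p1.
    """

    x: np.ndarray
    values: np.ndarray
    n_prune_iter: int = 0
    weights: np.ndarray | None = None

    def __post_init__(self):
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("condFDR values must lie in [0, 1]")
        if np.any(np.diff(self.values, axis=0) > 1e-12):
            raise ValueError("condFDR rows must be nonincreasing in -log10 p1")


@dataclass
class SharedLocus:
    """A clumped set of conjFDR-passing variants with a lead SNP."""

    index: int
    members: list[str]
    lead_snp: str
    lead_conjfdr: float
    chrom: object
    pos: int
    z1: float
    z2: float
    mapped_genes: list[str] = field(default_factory=list)
    concordant: bool | None = None

    def __post_init__(self):
        if self.lead_snp not in self.members:
            raise ValueError("lead SNP must be a member of its locus")


@dataclass
class DeResult:
    """Differential-expression test result for one gene."""

    gene: str
    test: str
    statistic: float
    p: float
    group_means: Mapping[str, float]
    normality_p: float
    called: bool
    alpha: float = 0.05
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate:
            if not (0 < self.p <= 1):
                raise ValueError("p must lie in (0, 1]")
            if self.called != (self.p < self.alpha):
                raise ValueError("called flag inconsistent with p and alpha")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_means"] = dict(self.group_means)
        return d
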