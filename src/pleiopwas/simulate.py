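"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of a two-trait GWAS study
with a protein-weight reference:

* an LD reference of block-diagonal AR(1) correlation (closed-form entries,
  so every LD-dependent computation is oracle-checkable),
* genotype draws whose empirical LD matches the panel (binomial marginals
  through a latent-Gaussian construction with Hermite-expansion correlation
  matching),
* protein abundance under sparse cis-genetic control with a stated
  cis-heritability,
* two traits' summary z-scores from a four-component causal mixture
  (shared / trait-1 only / trait-2 only / null) with LD-smeared effects and
  LD-correlated noise,
* case/control expression matrices with planted group shifts.

Every generator is a pure function of (config, seed); truth records carry
the planted state so downstream recovery can be scored without re-deriving
anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermeval
from scipy import stats
from scipy.special import factorial

from .config import ScenarioConfig
from .datatypes import (
    ExpressionMatrix,
    GwasSummary,
    LdReference,
    VariantPanel,
    two_sided_p,
)

_VARIANT_SPACING_BP = 1_000
_BLOCK_GAP_BP = 1_000_000
_NUCLEOTIDES = np.array(list("ACGT"))
# non-complementary alternatives for each reference allele, so simulated
# panels contain no strand-ambiguous variants
_SAFE_ALT = {"A": ["C", "G"], "C": ["A", "T"], "G": ["A", "T"], "T": ["C", "G"]}

_HERMITE_K = 25
_KS = np.arange(1, _HERMITE_K + 1)
_FACT = factorial(_KS)


# ---------------------------------------------------------------------------
# latent-Gaussian genotype machinery


def _genotype_thresholds(maf: float) -> tuple[float, float]:
    """Latent-normal cut points reproducing binomial(2, maf) marginals."""
    return (
        stats.norm.ppf((1 - maf) ** 2),
        stats.norm.ppf(1 - maf**2),
    )


def _hermite_coeffs(maf: float) -> np.ndarray:
    """Hermite coefficients a_k = E[G He_k(Z)] of the genotype step function.

    For G = 1{Z > t1} + 1{Z > t2} the coefficients have the closed form
    a_k = phi(t1) He_{k-1}(t1) + phi(t2) He_{k-1}(t2), which makes the
    genotype covariance under latent correlation r an explicit power series
    cov(G_i, G_j) = sum_k a_k(i) a_k(j) r^k / k!.
    """
    t1, t2 = _genotype_thresholds(maf)
    out = np.empty(_HERMITE_K)
    for k in _KS:
        basis = [0.0] * (k - 1) + [1.0]
        out[k - 1] = stats.norm.pdf(t1) * hermeval(t1, basis) + stats.norm.pdf(
            t2
        ) * hermeval(t2, basis)
    return out

def _solve_latent(coeffs: np.ndarray, target_cov: np.ndarray) -> np.ndarray:
    """Latent correlations giving the target genotype covariances (equal maf).

    Bisection on the monotone power series; targets above the series'
    maximum (comonotone coupling) saturate at the maximum.
    """
    c = coeffs * coeffs / _FACT
    lo = np.zeros_like(target_cov)
    hi = np.full_like(target_cov, 0.999999)
    reachable = target_cov < np.sum(c * hi[..., None] ** _KS, axis=-1)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = np.sum(c * mid[..., None] ** _KS, axis=-1)
        lower = f < target_cov
        lo = np.where(lower, mid, lo)
        hi = np.where(lower, hi, mid)
    return np.where(reachable, 0.5 * (lo + hi), 0.999999)


def _nearest_correlation(M: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped projection to the PSD correlation matrices."""
    w, V = np.linalg.eigh(M)
    if w.min() >= 0:
        return M
    w = np.clip(w, 1e-8, None)
    M2 = (V * w) @ V.T
    d = np.sqrt(np.diag(M2))
    return M2 / np.outer(d, d)


def _latent_block(maf: float, target_R: np.ndarray) -> np.ndarray:
    """Latent-Gaussian correlation matrix whose thresholded genotypes have
    (approximately) the target correlation matrix, at constant maf."""
    m = len(target_R)
    if m == 1:
        return np.ones((1, 1))
    var_g = 2 * maf * (1 - maf)
    coeffs = _hermite_coeffs(maf)
    # AR(1) targets depend on |i-j| only: one solve per lag
    lag_cov = target_R[0, 1:] * var_g
    latent_by_lag = _solve_latent(coeffs, lag_cov)
    latent_by_lag = np.where(target_R[0, 1:] <= 0, target_R[0, 1:], latent_by_lag)
    idx = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    full = np.concatenate([[1.0], latent_by_lag])
    return _nearest_correlation(full[idx])


def sample_genotypes(
    maf: float, target_R: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n genotype rows (values 0/1/2) with the target LD at constant maf."""
    lat = _latent_block(maf, target_R)
    L = np.linalg.cholesky(lat + 1e-12 * np.eye(len(lat)))
    Z = rng.standard_normal((n, len(lat))) @ L.T
    t1, t2 = _genotype_thresholds(maf)
    return (Z > t1).astype(float) + (Z > t2)


# ---------------------------------------------------------------------------
# panel and LD reference


def _ar1_matrix(m: int, rho: float) -> np.ndarray:
    if rho == 0:
        return np.eye(m)
    idx = np.arange(m)
    return rho ** np.abs(np.subtract.outer(idx, idx)).astype(float)


def simulate_ld_panel(config: ScenarioConfig) -> LdReference:
    """Generate the variant panel and per-block AR(1) correlation matrices.

    Blocks are laid out contiguously along chromosomes 1..22 with a large
    inter-block gap; MAF is drawn once per block (variants in tight LD share
    allele-frequency history, and very unequal MAFs bound the achievable
    genotype correlation below high LD targets).
    """
    rng = np.random.default_rng(config.seed)
    sizes = np.full(config.n_blocks, config.n_variants // config.n_blocks)
    sizes[: config.n_variants % config.n_blocks] += 1
    n_chrom = min(22, config.n_blocks)
    block_chrom = (np.arange(config.n_blocks) * n_chrom) // config.n_blocks + 1

    rows = []
    blocks = []
    pos_by_chrom: dict[int, int] = {}
    v = 0
    for b, m in enumerate(sizes):
        chrom = int(block_chrom[b])
        start = pos_by_chrom.get(chrom, 0) + _BLOCK_GAP_BP
        maf = rng.uniform(*config.maf_range)
        a1 = rng.choice(_NUCLEOTIDES, size=m)
        a2 = np.array([rng.choice(_SAFE_ALT[a]) for a in a1])
        for i in range(m):
            pos = start + i * _VARIANT_SPACING_BP
            rows.append((f"rs{v + 1:07d}", chrom, pos, a1[i], a2[i], maf, b))
            v += 1
        pos_by_chrom[chrom] = start + (m - 1) * _VARIANT_SPACING_BP
        blocks.append(_ar1_matrix(m, config.block_rho))

    panel = pd.DataFrame(
        rows, columns=["snp", "chrom", "pos", "a1", "a2", "maf", "block"]
    )
    return LdReference(VariantPanel(panel), blocks)


def gene_windows(ld: LdReference, config: ScenarioConfig) -> pd.DataFrame:
    """Deterministic gene placement: genes spread over blocks, each gene's
    cis window the variants within cis_window_bp/2 of its block's center
    (confined to the block, so the window LD is exactly the block LD)."""
    panel = ld.panel.table
    n_blocks = ld.n_blocks
    out = []
    for g in range(config.n_genes):
        block = (g * n_blocks) // config.n_genes if config.n_genes <= n_blocks else g % n_blocks
        in_block = panel.index[panel["block"] == block].to_numpy()
        center = in_block[len(in_block) // 2]
        cpos = int(panel.loc[center, "pos"])
        half = config.cis_window_bp // 2
        window = in_block[
            (panel.loc[in_block, "pos"] >= cpos - half)
            & (panel.loc[in_block, "pos"] <= cpos + half)
        ]
        out.append(
            {
                "gene": f"GENE{g + 1:04d}",
                "block": block,
                "chrom": panel.loc[center, "chrom"],
                "start": int(panel.loc[window, "pos"].min()),
                "end": int(panel.loc[window, "pos"].max()),
                "center_row": center,
                "rows": window,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# pQTL weight-training data


@dataclass
class PqtlTruth:
    """Planted cis architecture: true weight vector and causal ids per gene."""

    beta: dict[str, pd.Series]
    causal_ids: dict[str, list[str]]
    h2_cis: float


@dataclass
class PqtlTraining:
    genes: pd.DataFrame                      # gene, block, chrom, start, end
    genotypes: dict[str, np.ndarray]         # gene -> n_ref x m dosage matrix
    snp_ids: dict[str, list[str]]
    abundance: pd.DataFrame                  # genes x samples
    truth: PqtlTruth


def simulate_pqtl_training(
    ld: LdReference, config: ScenarioConfig, seed: int | None = None
) -> PqtlTraining:
    """Genotypes and protein abundance for weight training.

    Abundance = genotype @ beta_true + normal noise, with the noise variance
    chosen so the genetic fraction of the total variance equals h2_cis in
    expectation (using the panel's theoretical genotype covariance).
    """
    if config.h2_cis == 0 and config.n_causal_cis > 0:
        raise ValueError("h2_cis = 0 with n_causal_cis > 0 is contradictory")
    if config.h2_cis > 0 and config.n_causal_cis == 0:
        raise ValueError("h2_cis > 0 requires n_causal_cis > 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = gene_windows(ld, config)
    panel = ld.panel.table

    genotypes: dict[str, np.ndarray] = {}
    snp_ids: dict[str, list[str]] = {}
    beta_truth: dict[str, pd.Series] = {}
    causal: dict[str, list[str]] = {}
    abund_rows = []
    sample_names = [f"REF{i + 1:04d}" for i in range(config.n_ref)]

    for rec in genes.itertuples():
        rows = rec.rows
        m = len(rows)
        if config.n_causal_cis > m:
            raise ValueError(
                f"{rec.gene}: n_causal_cis={config.n_causal_cis} exceeds "
                f"cis-window size {m}"
            )
        ids = panel.loc[rows, "snp"].tolist()
        maf = float(panel.loc[rows[0], "maf"])
        sub_R = ld.submatrix(ids)
        G = sample_genotypes(maf, sub_R, config.n_ref, rng)

        beta = np.zeros(m)
        if config.n_causal_cis > 0:
            which = rng.choice(m, size=config.n_causal_cis, replace=False)
            beta[which] = rng.standard_normal(config.n_causal_cis)
            sd = np.sqrt(2 * maf * (1 - maf))
            var_g = float(beta @ (sub_R * sd * sd) @ beta)
            noise_var = var_g * (1 - config.h2_cis) / config.h2_cis
        else:
            var_g, noise_var = 0.0, 1.0
        y = G @ beta + rng.standard_normal(config.n_ref) * np.sqrt(noise_var)

        genotypes[rec.gene] = G
        snp_ids[rec.gene] = ids
        beta_truth[rec.gene] = pd.Series(beta, index=ids)
        causal[rec.gene] = [ids[i] for i in np.flatnonzero(beta)]
        abund_rows.append(pd.Series(y, index=sample_names, name=rec.gene))

    abundance = pd.DataFrame(abund_rows)
    truth = PqtlTruth(beta=beta_truth, causal_ids=causal, h2_cis=config.h2_cis)
    return PqtlTraining(
        genes=genes.drop(columns=["rows"]),
        genotypes=genotypes,
        snp_ids=snp_ids,
        abundance=abundance,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# bivariate GWAS summary statistics


@dataclass
class GwasTruth:
    """Causal classes and effect vectors behind a simulated trait pair."""

    causal_class: pd.Series            # per variant: null/shared/trait1/trait2
    beta1: np.ndarray
    beta2: np.ndarray
    planted_ids: list[str] = field(default_factory=list)


def simulate_bivariate_gwas(
    ld: LdReference,
    config: ScenarioConfig,
    seed: int | None = None,
    planted_shared: list[tuple[str, float]] | None = None,
) -> tuple[GwasSummary, GwasSummary, GwasTruth]:
    """Summary z-scores for two traits with controlled polygenic overlap.

    Causal status is a four-component mixture per variant; shared causal
    variants receive the identical effect in both traits (so genuinely
    pleiotropic signals have concordant directions, as in real comorbid
    trait pairs). Per block, z = sqrt(N) R beta + eps with eps ~ MVN(0, R):
    LD-smeared effects, LD-correlated noise, independent across traits.
    ``planted_shared`` adds fixed-effect shared variants on top.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panel = ld.panel.table
    n = len(panel)

    probs = [config.pi_shared, config.pi1, config.pi2]
    cls = rng.choice(4, size=n, p=probs + [1 - sum(probs)])
    beta1 = np.zeros(n)
    beta2 = np.zeros(n)
    shared = cls == 0
    b_shared = rng.standard_normal(shared.sum()) * config.sigma_beta
    beta1[shared] = b_shared
    beta2[shared] = b_shared
    beta1[cls == 1] = rng.standard_normal((cls == 1).sum()) * config.sigma_beta
    beta2[cls == 2] = rng.standard_normal((cls == 2).sum()) * config.sigma_beta

    planted_ids: list[str] = []
    if planted_shared:
        rows = ld.panel.rows_of([sid for sid, _ in planted_shared])
        for row, (sid, b) in zip(rows, planted_shared):
            beta1[row] = b
            beta2[row] = b
            cls[row] = 0
            planted_ids.append(sid)

    z1 = np.empty(n)
    z2 = np.empty(n)
    block_ids = panel["block"].to_numpy()
    start = 0
    for b, R in enumerate(ld.blocks):
        m = len(R)
        sl = slice(start, start + m)
        L = ld.cholesky(b)
        for z, beta, ngwas in ((z1, beta1, config.n_gwas1), (z2, beta2, config.n_gwas2)):
            mean = np.sqrt(ngwas) * (R @ beta[sl])
            z[sl] = mean + L @ rng.standard_normal(m)
        start += m

    class_names = np.array(["shared", "trait1", "trait2", "null"])
    truth = GwasTruth(
        causal_class=pd.Series(class_names[cls], index=panel["snp"].to_numpy()),
        beta1=beta1,
        beta2=beta2,
        planted_ids=planted_ids,
    )

    def summary(z, ngwas):
        tbl = panel[["snp", "chrom", "pos", "a1", "a2"]].copy()
        tbl["z"] = z
        tbl["p"] = two_sided_p(z)
        tbl["n"] = ngwas
        return GwasSummary(tbl)

    return summary(z1, config.n_gwas1), summary(z2, config.n_gwas2), truth


# ---------------------------------------------------------------------------
# expression matrices


def simulate_expression(
    n_genes: int,
    groups: list[tuple[str, int]],
    planted: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    gene_names: list[str] | None = None,
    baseline_sd: float = 1.0,
) -> ExpressionMatrix:
    """Log-scale expression with normal noise and planted group shifts.

    Shifts are expressed in units of the baseline (within-group) standard
    deviation, so ``-2.0`` plants a two-SD downregulation.
    """
    if gene_names is None:
        gene_names = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    group_labels = [g for g, _ in groups]
    planted = planted or {}
    for gene, shifts in planted.items():
        if gene not in gene_names:
            raise ValueError(f"planted effect references unknown gene: {gene}")
        for grp in shifts:
            if grp not in group_labels:
                raise ValueError(f"planted effect references unknown group: {grp}")

    rng = np.random.default_rng(seed)
    columns = []
    labels = []
    for grp, size in groups:
        for i in range(size):
            columns.append(f"{grp}{i + 1:03d}")
            labels.append(grp)

    base = rng.normal(8.0, 2.0, size=n_genes)
    values = base[:, None] + rng.standard_normal((n_genes, len(columns))) * baseline_sd
    values = pd.DataFrame(values, index=gene_names, columns=columns)
    for gene, shifts in planted.items():
        for grp, shift in shifts.items():
            cols = [c for c, lab in zip(columns, labels) if lab == grp]
            values.loc[gene, cols] += shift * baseline_sd
    return ExpressionMatrix(values, pd.Series(labels, index=columns))
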