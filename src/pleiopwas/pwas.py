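"""Cis-SNP weight training and the PWAS weighted z-score statistic.

A gene's association with a trait is tested by propagating its cis-SNP
weights w through the trait's GWAS z-scores:

    z_pwas = (w' z) / sqrt(w' R w)

where R is the cis-window LD matrix. The denominator is the variance of the
linear combination under the null, so z_pwas is standard normal when the
protein is unrelated to the trait regardless of the weights.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNetCV, LassoCV, Ridge, RidgeCV
from sklearn.model_selection import KFold

from .datatypes import (
    AMBIGUOUS_PAIRS,
    P_FLOOR,
    GwasSummary,
    LdReference,
    ProteinWeightModel,
    PwasResult,
    two_sided_p,
)

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("top1", "blup", "lasso", "enet")

_RIDGE_ALPHAS = np.logspace(-3, 4, 30)


def z_to_p(z: float) -> float:
    """Two-sided standard-normal tail probability of z, floored at 1e-300."""
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return float(two_sided_p(float(z)))


def _marginal_z(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-SNP marginal association z-scores of abundance on genotype."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    n = len(y)
    sx = Xc.std(axis=0, ddof=1)
    sy = yc.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / ((n - 1) * sx * sy)
        r = np.clip(np.nan_to_num(r), -0.999999, 0.999999)
        t = r * np.sqrt((n - 2) / (1 - r**2))
    return t


def _fit_top1(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Single best marginal SNP; weight = its marginal OLS coefficient."""
    zm = _marginal_z(X, y)
    best = int(np.argmax(np.abs(zm)))
    x = X[:, best] - X[:, best].mean()
    denom = x @ x
    w = np.zeros(X.shape[1])
    w[best] = (x @ (y - y.mean())) / denom if denom > 0 else 0.0
    return w


def _make_fitter(family: str, seed: int):
    if family == "top1":
        return _fit_top1
    if family == "blup":
        def fit(X, y):
            model = RidgeCV(alphas=_RIDGE_ALPHAS).fit(X, y)
            return Ridge(alpha=model.alpha_).fit(X, y).coef_
        return fit
    if family == "lasso":
        def fit(X, y):
            return LassoCV(cv=3, alphas=30, random_state=seed, max_iter=5000).fit(X, y).coef_
        return fit
    if family == "enet":
        def fit(X, y):
            return ElasticNetCV(
                cv=3, alphas=30, l1_ratio=0.5, random_state=seed, max_iter=5000
            ).fit(X, y).coef_
        return fit
    raise ValueError(f"unknown model family: {family}")


def fit_weights(
    genotypes: np.ndarray,
    abundance: np.ndarray,
    ld: LdReference | None,
    gene: str,
    snp_ids: list[str],
    a1: list[str] | None = None,
    a2: list[str] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    chrom: object = None,
    cis_start: int = 0,
    cis_end: int = 0,
) -> ProteinWeightModel:
    """Fit top1 / blup(ridge) / lasso / elastic-net cis weights for one gene.

    ``cv_r2`` per family is the out-of-fold R-squared from a seeded k-fold
    split (the penalty of each penalized family is re-tuned inside each
    training fold); the best model is the cv_r2 argmax among families whose
    final weight vector is not identically zero.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X = np.asarray(genotypes, float)
    y = np.asarray(abundance, float)
    if X.shape[0] != len(y):
        raise ValueError("genotype rows must match abundance length")
    if X.shape[1] != len(snp_ids):
        raise ValueError("genotype columns must match snp_ids")
    if a1 is None and ld is not None:
        sub = ld.panel.table.set_index("snp").loc[snp_ids]
        a1 = sub["a1"].tolist()
        a2 = sub["a2"].tolist()
    a1 = a1 or ["?"] * len(snp_ids)
    a2 = a2 or ["?"] * len(snp_ids)

    notes: list[str] = []
    keep = X.std(axis=0) > 0
    dropped = [s for s, k in zip(snp_ids, keep) if not k]
    if dropped:
        notes.append(f"dropped {len(dropped)} constant genotype columns")

    def model(weights, cv_r2, best, degenerate=False):
        return ProteinWeightModel(
            gene=gene,
            chrom=chrom,
            cis_start=cis_start,
            cis_end=cis_end,
            snp_ids=list(snp_ids),
            a1=list(a1),
            a2=list(a2),
            weights=weights,
            cv_r2=cv_r2,
            best_model=best,
            dropped_snps=dropped,
            degenerate=degenerate,
            notes=notes,
        )

    if y.std() == 0 or not keep.any():
        notes.append("degenerate input: constant abundance or all-constant genotypes")
        zeros = {f: np.zeros(len(snp_ids)) for f in MODEL_FAMILIES}
        return model(zeros, {f: np.nan for f in MODEL_FAMILIES}, None, degenerate=True)

    Xk = X[:, keep]
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xk))

    weights: dict[str, np.ndarray] = {}
    cv_r2: dict[str, float] = {}
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    for family in MODEL_FAMILIES:
        fitter = _make_fitter(family, seed)
        pred = np.empty_like(y)
        for tr, te in splits:
            w = fitter(Xk[tr], y[tr])
            mu = y[tr].mean() - Xk[tr].mean(axis=0) @ w
            pred[te] = Xk[te] @ w + mu
        cv_r2[family] = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
        full = np.zeros(len(snp_ids))
        full[keep] = fitter(Xk, y)
        weights[family] = full

    eligible = [f for f in MODEL_FAMILIES if np.any(weights[f] != 0)]
    skipped = set(MODEL_FAMILIES) - set(eligible)
    for f in sorted(skipped):
        logger.warning("%s: %s produced an all-zero weight vector; falling back", gene, f)
        notes.append(f"{f} all-zero; excluded from model selection")
    best = max(eligible, key=lambda f: cv_r2[f])
    return model(weights, cv_r2, best)


def _align_alleles(
    model: ProteinWeightModel,
    gwas: GwasSummary,
    drop_ambiguous: bool = True,
) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    """Match model SNPs into the GWAS, flipping z where alleles are swapped.

    Returns (kept ids, kept weight mask indices, aligned z, dropped ids).
    """
    gt = gwas.table.set_index("snp")
    kept_ids: list[str] = []
    kept_idx: list[int] = []
    z_aligned: list[float] = []
    dropped: list[str] = []
    has_a2 = "a2" in gt.columns
    for i, (sid, wa1, wa2) in enumerate(zip(model.snp_ids, model.a1, model.a2)):
        if sid not in gt.index:
            dropped.append(sid)
            continue
        if drop_ambiguous and (wa1, wa2) in AMBIGUOUS_PAIRS:
            dropped.append(sid)
            continue
        ga1 = gt.at[sid, "a1"]
        ga2 = gt.at[sid, "a2"] if has_a2 else None
        z = float(gt.at[sid, "z"])
        if ga1 == wa1 and (ga2 is None or ga2 == wa2):
            pass
        elif ga1 == wa2 and (ga2 is None or ga2 == wa1):
            z = -z
        else:
            dropped.append(sid)
            continue
        kept_ids.append(sid)
        kept_idx.append(i)
        z_aligned.append(z)
    return kept_ids, np.array(kept_idx, int), np.array(z_aligned), dropped


def pwas_association(
    model: ProteinWeightModel,
    gwas: GwasSummary,
    ld: LdReference,
    model_family: str = "best",
    min_overlap: float = 0.5,
    drop_ambiguous: bool = True,
) -> PwasResult:
    """PWAS statistic z_pwas = w'z / sqrt(w'Rw) for one gene and one trait.

    Weights of SNPs absent from the GWAS (or strand-ambiguous) are set to
    zero and the denominator is recomputed on the present subset; genes with
    too few matched SNPs or a degenerate quadratic form are skipped with an
    explicit record rather than an error.
    """
    if model.degenerate:
        return PwasResult(model.gene, np.nan, np.nan, skipped=True,
                          skip_reason="degenerate weight model")
    family = model.best_model if model_family == "best" else model_family
    if family not in model.weights:
        raise ValueError(f"{model.gene}: no weights for model family {family}")
    w_full = np.asarray(model.weights[family], float)

    kept_ids, kept_idx, z, dropped = _align_alleles(model, gwas, drop_ambiguous)
    if len(kept_ids) < min_overlap * len(model.snp_ids):
        return PwasResult(
            model.gene, np.nan, np.nan, skipped=True, model_used=family,
            skip_reason=f"only {len(kept_ids)}/{len(model.snp_ids)} SNPs matched",
        )
    w = w_full[kept_idx]
    R = ld.submatrix(kept_ids)
    denom = float(w @ R @ w)
    if denom <= 1e-12:
        return PwasResult(
            model.gene, np.nan, np.nan, skipped=True, model_used=family,
            skip_reason="degenerate weight (w'Rw ~ 0 on matched SNPs)",
        )
    z_pwas = float(w @ z) / np.sqrt(denom)
    return PwasResult(
        model.gene, z_pwas, z_to_p(z_pwas), model_used=family,
        n_snps_used=len(kept_ids),
    )


def flag_significant(
    results: list[PwasResult],
    method: str = "bh_fdr",
    alpha: float = 0.05,
    m: int | None = None,
) -> list[PwasResult]:
    """Set the per-gene significance flags under Bonferroni or BH step-up.

    ``m`` lets the correction span more tests than were computed here (for
    example all proteins in a reference panel, not only those reported).
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    tested = [r for r in results if not r.skipped]
    if m is None:
        m = len(tested)
    if m < len(tested):
        raise ValueError(f"m={m} smaller than the {len(tested)} tested genes")
    if method == "bonferroni":
        for r in tested:
            r.significant = bool(r.p < alpha / m)
    elif method == "bh_fdr":
        order = np.argsort([r.p for r in tested])
        p_sorted = np.array([tested[i].p for i in order])
        ranks = np.arange(1, len(tested) + 1)
        adj = np.minimum.accumulate((p_sorted * m / ranks)[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        for i, a in zip(order, adj):
            tested[i].significant = bool(a < alpha)
    else:
        raise ValueError(f"unknown multiple-testing method: {method}")
    return results
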