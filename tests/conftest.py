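import numpy as np
import pandas as pd
import pytest

import pleiopwas as pp
from pleiopwas.config import ScenarioConfig
from pleiopwas.datatypes import GwasSummary, LdReference, VariantPanel


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(
        n_variants=500, n_blocks=10, n_genes=5, n_ref=200, seed=42
    )


@pytest.fixture(scope="session")
def small_ld(small_config):
    return pp.simulate_ld_panel(small_config)


@pytest.fixture(scope="session")
def small_training(small_ld, small_config):
    return pp.simulate_pqtl_training(small_ld, small_config)


def toy_panel(n: int, block_sizes=None, rho=0.0, chrom=1, maf=0.3) -> LdReference:
    """Hand-sized LD reference for oracle tests."""
    if block_sizes is None:
        block_sizes = [n]
    assert sum(block_sizes) == n
    rows = []
    v = 0
    blocks = []
    for b, m in enumerate(block_sizes):
        for i in range(m):
            rows.append((f"snp{v + 1:03d}", chrom, 1000 * (v + 1), "A", "G", maf, b))
            v += 1
        idx = np.arange(m)
        R = rho ** np.abs(np.subtract.outer(idx, idx)).astype(float) if rho else np.eye(m)
        blocks.append(R)
    panel = VariantPanel(
        pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2", "maf", "block"])
    )
    return LdReference(panel, blocks)


def gwas_from_p(ld: LdReference, p: np.ndarray, n: int = 1000) -> GwasSummary:
    """GWAS summary with prescribed p-values (z chosen consistently)."""
    from scipy import stats

    p = np.asarray(p, float)
    z = stats.norm.isf(p / 2)  # arbitrary positive sign
    tbl = ld.panel.table[["snp", "chrom", "pos", "a1", "a2"]].copy()
    tbl["z"] = z
    tbl["p"] = p
    tbl["n"] = n
    # constructor re-checks p/z consistency
    return GwasSummary(tbl)


def gwas_from_z(ld: LdReference, z: np.ndarray, n: int = 1000) -> GwasSummary:
    tbl = ld.panel.table[["snp", "chrom", "pos", "a1", "a2"]].copy()
    tbl["z"] = np.asarray(z, float)
    tbl["n"] = n
    return GwasSummary.from_z(tbl)
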