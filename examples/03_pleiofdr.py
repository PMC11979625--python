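"""Conditional/conjunctional FDR analysis of a simulated trait pair.

Plants five strong shared-risk clusters, builds the reciprocal condFDR
lookups with LD-pruning weights, takes the per-variant conjFDR maximum,
clumps passing variants into loci, and prints the shared-locus table with
direction-of-effect concordance.
"""

import numpy as np

import pleiopwas as pp

cfg = pp.ScenarioConfig(pi_shared=0, pi1=0, pi2=0, seed=5)  # 20000 variants
ld = pp.simulate_ld_panel(cfg)
panel = ld.panel.table

planted = [panel.loc[panel["block"] == b, "snp"].iloc[50]
           for b in (20, 60, 100, 140, 180)]
beta = 6.5 / np.sqrt(min(cfg.n_gwas1, cfg.n_gwas2))
gwas1, gwas2, _ = pp.simulate_bivariate_gwas(
    ld, cfg, planted_shared=[(s, beta) for s in planted]
)

qq = pp.conditional_qq(gwas1, gwas2)
print("conditional Q-Q mean shift (observed - expected -log10 p):")
for thr, shift in qq.mean_shift().items():
    print(f"  trait-2 p <= {thr:<6g}: {shift:+.3f}")
print("-> the shift grows as the conditioning stratum tightens: enrichment.\n")

weights = pp.random_prune(ld, r2_max=0.1, n_iter=100, seed=5)
c12 = pp.assign_condfdr(gwas1, gwas2, pp.build_condfdr_lookup(gwas1, gwas2, weights))
c21 = pp.assign_condfdr(gwas2, gwas1, pp.build_condfdr_lookup(gwas2, gwas1, weights))
conj = pp.conjfdr(c12, c21)

loci = pp.define_loci(conj, ld, gwas1, gwas2, threshold=0.01, r2_clump=0.1)
loci = pp.concordance_check(loci, gwas1, gwas2)
print(f"{int((conj < 0.01).sum())} variants at conjFDR < 0.01 in {len(loci)} loci:")
print(pp.loci_table(loci).to_string(index=False))
print(f"\nplanted clusters recovered: "
      f"{sum(bool(set(l.members) & set(planted)) for l in loci)} of {len(planted)}")
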