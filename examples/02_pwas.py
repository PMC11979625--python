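"""Train cis-SNP weight models and test genes with the PWAS statistic.

Fits top1 / ridge / lasso / elastic-net weights for each gene's cis window
on simulated reference genotypes, then combines the best model's weights
with a trait's GWAS z-scores: z_pwas = w'z / sqrt(w'Rw). One gene is given
a genuine protein-mediated trait effect; it should dominate the ranking.
"""

import numpy as np

import pleiopwas as pp

cfg = pp.ScenarioConfig(n_variants=2000, n_blocks=20, n_genes=10,
                        h2_cis=0.3, n_ref=400, seed=3)
ld = pp.simulate_ld_panel(cfg)
training = pp.simulate_pqtl_training(ld, cfg)

# give the first gene's causal cis-SNP a real effect on the trait
planted_gene = training.genes["gene"].iloc[0]
causal_snp = training.truth.causal_ids[planted_gene][0]
beta = 7.0 / np.sqrt(cfg.n_gwas1)
gwas, _, _ = pp.simulate_bivariate_gwas(
    ld, cfg.replace(pi_shared=0, pi1=0, pi2=0), planted_shared=[(causal_snp, beta)]
)

print(f"{'gene':10s} {'model':6s} {'cv_r2':>6s} {'z_pwas':>8s} {'p':>10s}")
results = []
for rec in training.genes.itertuples():
    model = pp.fit_weights(
        training.genotypes[rec.gene],
        training.abundance.loc[rec.gene].to_numpy(),
        ld, rec.gene, training.snp_ids[rec.gene], seed=0,
    )
    res = pp.pwas_association(model, gwas, ld)
    results.append(res)
    print(f"{rec.gene:10s} {res.model_used:6s} "
          f"{model.cv_r2[model.best_model]:6.3f} {res.z_pwas:8.2f} {res.p:10.2e}")

pp.flag_significant(results, method="bh_fdr", alpha=0.05)
sig = [r.gene for r in results if r.significant]
print(f"\nBH-significant at FDR 0.05: {sig}")
print(f"planted gene was {planted_gene}: the statistic recovers the gene whose")
print("cis-regulated protein abundance genuinely mediates trait risk.")
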