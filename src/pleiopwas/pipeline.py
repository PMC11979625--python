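"""End-to-end pipeline: simulate -> fit-weights -> pwas -> pleiofdr -> de.

Chains the stages on a synthetic scenario and emits a combined report: the
per-trait PWAS tables and their overlap, the shared loci with mapped genes,
the differential-expression calls, and the three-way convergence set (genes
flagged simultaneously by all three stages).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as de_mod
from . import io as io_mod
from . import pleiofdr as pf
from . import pwas as pw
from . import simulate as sim
from .config import PipelineConfig, dump_pipeline_config

logger = logging.getLogger(__name__)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the combined report.

    Identical config (including seeds) produces an identical report. Any
    stage failure is re-raised annotated with the stage name.
    """
    report: dict = {"stages_run": [], "seed": config.seed,
                    "config": dataclasses.asdict(config)}
    report["config"]["scenario"]["maf_range"] = list(config.scenario.maf_range)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        dump_pipeline_config(config, out_dir / "resolved_config.yaml")

    seeds = _spawn_seeds(config.seed, 4)
    scenario = config.scenario.replace(seed=seeds[0])
    state: dict = {}

    def stage(name, enabled, fn):
        if not enabled:
            return
        t0 = time.time()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        report["stages_run"].append(name)
        logger.info("stage %s finished in %.1f s", name, time.time() - t0)

    # ---- simulate -------------------------------------------------------
    def do_simulate():
        ld = sim.simulate_ld_panel(scenario)
        training = sim.simulate_pqtl_training(ld, scenario, seed=seeds[1])
        planted_genes = training.genes["gene"].tolist()[: config.planted.n_genes]
        planted_shared = []
        beta = config.planted.lead_z / np.sqrt(min(scenario.n_gwas1, scenario.n_gwas2))
        for g in planted_genes:
            causal = training.truth.causal_ids[g]
            if not causal:
                raise RuntimeError(f"planted gene {g} has no causal cis-SNP")
            planted_shared.append((causal[0], beta))
        gwas1, gwas2, gwas_truth = sim.simulate_bivariate_gwas(
            ld, scenario, seed=seeds[2], planted_shared=planted_shared
        )
        planted_expr = {
            g: {config.de.case_group: config.planted.expression_shift}
            for g in planted_genes
        }
        expr = sim.simulate_expression(
            n_genes=scenario.n_genes,
            groups=[(config.de.case_group, config.de.n_case),
                    (config.de.control_group, config.de.n_control)],
            planted=planted_expr,
            seed=seeds[3],
            gene_names=training.genes["gene"].tolist(),
        )
        annotation = training.genes[["gene", "chrom", "start", "end"]].copy()
        state.update(ld=ld, training=training, gwas1=gwas1, gwas2=gwas2,
                     expr=expr, annotation=annotation)
        report["planted_genes"] = planted_genes
        report["n_variants"] = len(ld.panel)
        report["n_genes"] = scenario.n_genes
        if out_dir:
            io_mod.write_gwas(gwas1, out_dir / "gwas_trait1.tsv")
            io_mod.write_gwas(gwas2, out_dir / "gwas_trait2.tsv")
            io_mod.write_panel(ld.panel, out_dir / "panel.tsv")
            io_mod.write_expression(expr, out_dir / "expression.tsv")
            io_mod.write_annotation_bed(annotation, out_dir / "genes.bed")
            io_mod.write_json(
                {
                    "planted_genes": planted_genes,
                    "planted_variants": gwas_truth.planted_ids,
                    "causal_cis": training.truth.causal_ids,
                    "causal_class": gwas_truth.causal_class.value_counts().to_dict(),
                },
                out_dir / "truth.json",
            )

    stage("simulate", config.stages.simulate, do_simulate)

    # ---- fit-weights ----------------------------------------------------
    def do_fit():
        training = state["training"]
        models = []
        for rec in training.genes.itertuples():
            models.append(
                pw.fit_weights(
                    training.genotypes[rec.gene],
                    training.abundance.loc[rec.gene].to_numpy(),
                    state["ld"],
                    rec.gene,
                    training.snp_ids[rec.gene],
                    k_folds=config.pwas.k_folds,
                    seed=config.seed,
                    chrom=rec.chrom,
                    cis_start=rec.start,
                    cis_end=rec.end,
                )
            )
        state["models"] = models
        if out_dir:
            io_mod.write_weights(models, out_dir / "weights")

    stage("fit_weights", config.stages.fit_weights, do_fit)

    # ---- pwas -----------------------------------------------------------
    def do_pwas():
        tables = {}
        sig = {}
        for name, gwas in (("trait1", state["gwas1"]), ("trait2", state["gwas2"])):
            results = [
                pw.pwas_association(
                    m, gwas, state["ld"],
                    model_family=config.pwas.model,
                    min_overlap=config.pwas.min_overlap,
                )
                for m in state["models"]
            ]
            pw.flag_significant(results, method=config.pwas.mt_method,
                                alpha=config.pwas.alpha)
            tbl = pd.DataFrame([dataclasses.asdict(r) for r in results])
            tables[name] = tbl
            sig[name] = set(tbl.loc[tbl["significant"].fillna(False), "gene"])
            if out_dir:
                io_mod._to_tsv(tbl, out_dir / f"pwas_{name}.tsv")
        overlap = sorted(sig["trait1"] & sig["trait2"])
        state["pwas_tables"] = tables
        state["pwas_overlap"] = overlap
        report["pwas_significant_trait1"] = sorted(sig["trait1"])
        report["pwas_significant_trait2"] = sorted(sig["trait2"])
        report["pwas_overlap"] = overlap

    stage("pwas", config.stages.pwas, do_pwas)

    # ---- pleiofdr -------------------------------------------------------
    def do_pleiofdr():
        ld, g1, g2 = state["ld"], state["gwas1"], state["gwas2"]
        opts = config.pleiofdr
        if config.scenario.block_rho > 0:
            weights = pf.random_prune(ld, opts.r2_prune, opts.prune_iters,
                                      seed=config.seed)
        else:
            weights = None
        look12 = pf.build_condfdr_lookup(g1, g2, weights, opts.grid_max, opts.grid_n)
        look21 = pf.build_condfdr_lookup(g2, g1, weights, opts.grid_max, opts.grid_n)
        cond12 = pf.assign_condfdr(g1, g2, look12)
        cond21 = pf.assign_condfdr(g2, g1, look21)
        conj = pf.conjfdr(cond12, cond21)
        loci = pf.define_loci(conj, ld, g1, g2,
                              threshold=opts.conjfdr_threshold,
                              r2_clump=opts.r2_clump)
        flank = opts.gene_flank_bp
        loci = pf.map_genes(loci, state["annotation"], flank=flank)
        loci = pf.concordance_check(loci, g1, g2)
        qq = pf.conditional_qq(g1, g2)
        state["conj"] = conj
        state["loci"] = loci
        locus_tbl = pf.loci_table(loci)
        report["n_conjfdr_snps"] = int((conj < opts.conjfdr_threshold).sum())
        report["n_loci"] = len(loci)
        report["loci"] = locus_tbl.to_dict("records")
        report["locus_genes"] = sorted(
            {g for l in loci for g in l.mapped_genes}
        )
        report["qq_mean_shift"] = qq.mean_shift()
        if out_dir:
            per_variant = pd.DataFrame(
                {
                    "SNP": conj.index,
                    "p1": g1.indexed("p").loc[conj.index].to_numpy(),
                    "p2": g2.indexed("p").loc[conj.index].to_numpy(),
                    "condfdr_1_2": cond12.loc[conj.index].to_numpy(),
                    "condfdr_2_1": cond21.loc[conj.index].to_numpy(),
                    "conjfdr": conj.to_numpy(),
                }
            )
            io_mod._to_tsv(per_variant, out_dir / "pleiofdr_per_variant.tsv")
            io_mod._to_tsv(locus_tbl, out_dir / "loci.tsv")
            from . import plots

            ax = plots.plot_conditional_qq(qq)
            ax.figure.savefig(out_dir / "conditional_qq.png", dpi=120)
            ax2 = plots.plot_manhattan(conj, ld.panel.table, loci,
                                       threshold=opts.conjfdr_threshold)
            ax2.figure.savefig(out_dir / "manhattan_conjfdr.png", dpi=120)

    stage("pleiofdr", config.stages.pleiofdr, do_pleiofdr)

    # ---- de -------------------------------------------------------------
    def do_de():
        expr = state["expr"]
        groups = (config.de.case_group, config.de.control_group)
        results = [
            de_mod.two_group_test(expr, g, groups, alpha=config.de.alpha)
            for g in expr.genes
        ]
        tbl = pd.DataFrame([r.as_dict() for r in results])
        tbl["p_adj"] = de_mod.bh_adjust(tbl["p"].to_numpy())
        down = tbl.apply(
            lambda r: r["group_means"][groups[0]] < r["group_means"][groups[1]],
            axis=1,
        )
        called = tbl.loc[tbl["called"], "gene"].tolist()
        state["de_table"] = tbl
        report["de_called"] = called
        report["de_called_down"] = tbl.loc[tbl["called"] & down, "gene"].tolist()
        if out_dir:
            flat = tbl.drop(columns=["group_means"]).assign(
                **{f"mean_{g}": tbl["group_means"].map(lambda d: d[g]) for g in groups}
            )
            io_mod._to_tsv(flat, out_dir / "de_results.tsv")

    stage("de", config.stages.de, do_de)

    # ---- convergence ----------------------------------------------------
    if {"pwas", "pleiofdr", "de"}.issubset(report["stages_run"]):
        report["convergent_genes"] = sorted(
            set(report["pwas_overlap"])
            & set(report["locus_genes"])
            & set(report["de_called_down"])
        )
    if out_dir:
        io_mod.write_json(report, out_dir / "report.json")
    return report
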