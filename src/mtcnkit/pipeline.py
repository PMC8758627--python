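"""End-to-end pipeline: synthetic cohort → copy number → GWAS → downstream.

Stages run in dependency order (synthdata → mtcn → assoc → finemap →
pheclust/genesets → mito); each stage writes its TSV outputs under the run
directory and records its headline numbers in the run report.  All
randomness flows from the configuration seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, copynum, finemap, genesets, mito, pheclust, synthdata
from .io import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


class StageDependencyError(RuntimeError):
    """An enabled stage is missing the output of an upstream stage."""


def _require(state: dict, key: str, stage: str, upstream: str):
    if key not in state:
        raise StageDependencyError(
            f"stage {stage!r} requires output of stage {upstream!r} "
            f"(missing {key!r})")
    return state[key]


def _gene_catalog(n_snps: int, spacing: int = 5000) -> pd.DataFrame:
    """Synthetic gene catalog tiling the simulated chromosome."""
    span = n_snps * spacing
    starts = np.arange(0, span, 100_000)
    return pd.DataFrame({
        "gene": [f"GENE{j:03d}" for j in range(len(starts))],
        "start": starts + 10_000,
        "end": starts + 40_000,
    })


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write(outdir / "resolved_config.yaml")
    rng = np.random.default_rng(config.seed)
    state: dict = {}
    report: dict = {"seed": config.seed}

    if config.stages.get("synthdata"):
        sim_cfg = synthdata.SimulationConfig(
            n_individuals=config.n_individuals, n_snps=config.n_snps,
            n_mtsnps=config.n_mtsnps, n_traits=config.n_traits,
            mito_hap_trait_beta=0.5, hap_log_hr=0.4, seed=config.seed)
        cohort = synthdata.simulate_cohort(sim_cfg)
        synthdata.write_cohort_tsv(cohort, outdir / "cohort")
        state["cohort"] = cohort
        report["synthdata"] = {"n_individuals": config.n_individuals,
                               "n_snps": config.n_snps}

    if config.stages.get("mtcn"):
        cohort = _require(state, "cohort", "mtcn", "synthdata")
        mt_int, mask, nuc_int = synthdata.simulate_probe_intensities(cohort)
        raw = copynum.raw_mtcn_from_probes(mt_int, mask)
        comps = copynum.technical_components(nuc_int, n_components=5)
        adj, k_used = copynum.stepwise_component_adjust(raw, comps)

        reads = synthdata.simulate_read_counts(cohort)
        n_overlap = max(30, int(config.wes_overlap_fraction * len(cohort.individuals)))
        overlap = cohort.individuals[:n_overlap]
        wes = copynum.mtcn_from_read_counts(
            reads.loc[overlap, "mt_reads"], reads.loc[overlap, "total_reads"])
        calibrated, fit = copynum.calibrate_array_to_wes(adj, wes)

        selected = copynum.select_cell_count_covariates(
            calibrated, cohort.cell_counts, seed=config.seed)
        covars = pd.concat([cohort.covariates,
                            cohort.cell_counts[selected]], axis=1)
        metric = copynum.standardize_residuals(calibrated, covars)
        metric_df = pd.DataFrame({"raw": raw, "adjusted": metric.adjusted,
                                  "assay": "array"})
        metric_df.to_csv(outdir / "mtcn_metric.tsv", sep="\t")
        state["metric"] = metric
        report["mtcn"] = {
            "n_components_used": k_used,
            "calibration_slope": fit["slope"],
            "selected_cell_counts": selected,
            "cor_adjusted_truth": float(np.corrcoef(
                metric.adjusted.dropna(),
                cohort.latent.loc[metric.adjusted.dropna().index])[0, 1]),
        }

    if config.stages.get("assoc"):
        cohort = _require(state, "cohort", "assoc", "synthdata")
        metric = _require(state, "metric", "assoc", "mtcn")
        meta = cohort.snp_positions.rename(columns={"id": "id"})
        stats = assoc.single_variant_assoc(
            cohort.nuclear_genotypes, metric.adjusted,
            cohort.covariates, variant_meta=meta)
        stats.to_csv(outdir / "gwas_stats.tsv", sep="\t", index=False)
        genotyped = set(meta.loc[meta["genotyped"], "id"])
        loci = assoc.identify_loci(stats, genotyped_set=genotyped)
        lam = assoc.genomic_inflation(stats["p"])
        state["gwas_stats"] = stats
        state["loci"] = [l for l in loci if l.retained]
        report["assoc"] = {"lambda_gc": lam,
                           "n_loci": len(loci),
                           "n_retained": len(state["loci"])}

    if config.stages.get("finemap"):
        stats = _require(state, "gwas_stats", "finemap", "assoc")
        loci = _require(state, "loci", "finemap", "assoc")
        genes = _gene_catalog(config.n_snps)
        assignments, coloc_pp4 = [], []
        fm_rng = np.random.default_rng(rng.integers(2**31))
        for locus in loci:
            win = stats[(stats["pos"] >= locus.start)
                        & (stats["pos"] <= locus.end)].copy()
            labf = finemap.wakefield_abf(win["beta"].to_numpy(),
                                         win["se"].to_numpy())
            w = np.exp(labf - labf.max())
            pips = pd.Series(w / w.sum(), index=win["id"])
            cs = finemap.credible_set_from_pips(pips, locus_id=locus.lead)
            final_lead = finemap.select_final_lead(locus.lead, cs)
            lead_pos = int(stats.set_index("id").loc[final_lead, "pos"])
            # synthetic eQTL sharing the causal signal for the nearest gene
            eqtl = win[["id", "pos", "beta", "se"]].copy()
            eqtl["beta"] = 1.5 * eqtl["beta"] + fm_rng.normal(
                0, 0.2 * eqtl["se"], len(eqtl))
            eqtl["p"] = finemap.rescale_extreme_z(
                (eqtl["beta"] / eqtl["se"]).to_numpy())
            res = finemap.coloc_abf(win, eqtl, locus_id=locus.lead,
                                    gene_id="nearest")
            coloc_pp4.append(res.pp4)
            assignments.append(finemap.assign_gene(
                locus.lead, lead_pos, cs.variants, None, [], None, genes))
        state["assignments"] = assignments
        state["gene_catalog"] = genes
        pd.DataFrame([{"locus": a.locus_id, "genes": ";".join(a.genes),
                       "tier": a.tier} for a in assignments]
                     ).to_csv(outdir / "gene_assignments.tsv", sep="\t", index=False)
        report["finemap"] = {
            "n_assigned": len(assignments),
            "mean_pp4": float(np.mean(coloc_pp4)) if coloc_pp4 else float("nan"),
        }

    if config.stages.get("pheclust"):
        cohort = _require(state, "cohort", "pheclust", "synthdata")
        metric = _require(state, "metric", "pheclust", "mtcn")
        stats = _require(state, "gwas_stats", "pheclust", "assoc")
        scan = pheclust.phewas_scan(metric.adjusted, cohort.traits,
                                    cohort.covariates)
        scan.to_csv(outdir / "phewas.tsv", sep="\t", index=False)
        truth_snps = sorted(cohort.truth.loc[cohort.truth["trait"] == "mtcn",
                                             "snp"].unique())
        snp_beta, _ = pheclust.snp_trait_betas(
            cohort.nuclear_genotypes[truth_snps], cohort.traits,
            cohort.covariates)
        matrix = pheclust.build_scaled_matrix(
            snp_beta, stats[stats["id"].isin(truth_snps)])
        cc = pheclust.ClusterConfig(min_pts=min(10, max(2, len(matrix.matrix) // 6)))
        labels, embedding, _ = pheclust.embed_and_cluster(matrix, cc)
        labels.to_frame().to_csv(outdir / "cluster_labels.tsv", sep="\t")
        embedding.to_csv(outdir / "umap_embedding.tsv", sep="\t")
        ench_rng = np.random.default_rng(rng.integers(2**31))
        results = pheclust.enrichment_scan(matrix, labels,
                                           n_perm=config.n_perm_enrichment,
                                           rng=ench_rng)
        thr, _ = pheclust.studywide_threshold(
            matrix, labels, n_outer=config.n_outer_threshold,
            n_perm_inner=max(200, config.n_perm_enrichment // 10),
            rng=ench_rng)
        for r in results:
            r.studywide_significant = r.p <= thr
        pd.DataFrame([r.__dict__ for r in results]).to_csv(
            outdir / "cluster_enrichment.tsv", sep="\t", index=False)
        state["labels"] = labels
        state["truth_cluster"] = cohort.truth[
            cohort.truth["trait"] == "mtcn"].set_index("snp")["cluster"]
        report["pheclust"] = {
            "n_traits_selected": int(scan["selected"].sum()),
            "n_clusters": int(len(set(labels) - {-1})),
            "studywide_threshold": thr,
            "n_studywide_significant": int(sum(r.studywide_significant
                                               for r in results)),
        }

    if config.stages.get("genesets"):
        assignments = _require(state, "assignments", "genesets", "finemap")
        genes_df = _require(state, "gene_catalog", "genesets", "finemap")
        universe = list(genes_df["gene"])
        assigned = sorted({g for a in assignments for g in a.genes})
        gs_rng = np.random.default_rng(rng.integers(2**31))
        # synthetic ontology: one term per block of genes + a term covering
        # the assigned genes, so a real enrichment signal exists
        ann_rows = [{"term": "assigned_module", "gene": g} for g in assigned]
        for t in range(10):
            members = gs_rng.choice(universe, size=min(12, len(universe)),
                                    replace=False)
            ann_rows += [{"term": f"term_{t}", "gene": g} for g in members]
        annotation = pd.DataFrame(ann_rows)
        if assignments:
            retained, _ = genesets.robust_terms(
                assignments, annotation, n_iter=config.n_geneset_iter,
                retain_min=int(0.8 * config.n_geneset_iter),
                n_perm=config.n_perm_cutoff, rng=gs_rng, universe=universe)
        else:
            retained = pd.Series(dtype=int)
        fisher_p, table = genesets.fisher_set_enrichment(
            assigned, target_set=assigned[: max(1, len(assigned) // 2)],
            universe=universe)
        retained.rename("pass_count").to_csv(outdir / "robust_terms.tsv", sep="\t")
        report["genesets"] = {"n_retained_terms": int(len(retained)),
                              "fisher_p": fisher_p,
                              "overlap": int(table[0, 0])}

    if config.stages.get("mito"):
        cohort = _require(state, "cohort", "mito", "synthdata")
        metric = _require(state, "metric", "mito", "mtcn")
        mito_rng = np.random.default_rng(rng.integers(2**31))
        traits = pd.concat([cohort.traits.iloc[:, :3],
                            metric.adjusted.rename("mtcn")], axis=1)
        cov = mito.with_age_squared(cohort.covariates)
        scan = mito.mtsnp_scan(cohort.mito_genotypes, traits, cov,
                               cohort.array_batch)
        scan.to_csv(outdir / "mtsnp_scan.tsv", sep="\t", index=False)
        thr, _ = mito.dummy_trait_threshold(
            cohort.mito_genotypes, cov, cohort.array_batch,
            n_dummy=config.n_dummy_traits, rank=config.dummy_rank,
            n_traits=config.n_traits + 1, rng=mito_rng)
        # credible sets from single-effect ABF fine-mapping of trait_0
        t0 = scan[scan["trait"] == "trait_0"].copy()
        labf = finemap.wakefield_abf(t0["beta"].to_numpy(), t0["se"].to_numpy())
        w = np.exp(labf - labf.max())
        pips = pd.Series(w / w.sum(), index=t0["snp"])
        both = (cohort.mito_meta.set_index("id")["genotyped_ukbb"]
                & cohort.mito_meta.set_index("id")["genotyped_ukbl"])
        blocks = np.array_split(np.arange(len(pips)), 6)
        css = []
        for j, b in enumerate(blocks):
            block_pips = pips.iloc[b]
            block_pips = block_pips / block_pips.sum()
            cs = finemap.credible_set_from_pips(
                block_pips, coverage=0.9, locus_id=f"cs{j}")
            if any(both.get(v, False) for v in cs.variants):
                css.append(cs)
            else:
                logger.warning("block %d: no dual-array SNP in credible set; "
                               "block skipped", j)
        haps = mito.build_haplotypes(cohort.mito_genotypes, css, both)
        p_anova, effects = mito.haplotype_anova(
            cohort.traits["trait_0"], haps, cov)
        cox = mito.cox_mortality(haps, cohort.survival,
                                 cohort.covariates[["age", "sex"]], mode="all")
        haps.labels.rename("haplotype").to_csv(outdir / "haplotypes.tsv", sep="\t")
        report["mito"] = {
            "studywide_threshold": thr,
            "n_haplotypes": int(len(haps.frequencies)),
            "anova_p": p_anova,
            "cox_global_p": cox["global_p"],
            "n_events": cox["n_events"],
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
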