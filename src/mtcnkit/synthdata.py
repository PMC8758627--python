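"""Seeded synthetic cohorts for exercising the mtDNA-CN pipeline.

The generator emulates the data structures a blood-derived mtDNA-CN study
rests on: diploid nuclear genotypes with blockwise linkage disequilibrium,
haploid mitochondrial genotypes built from a small set of haplotype backbones,
a latent true copy number per individual that drives array probe intensities
(with batch/plate artifacts), mitochondrial read fractions and qPCR ΔCt
values, cell counts sharing a confounding factor with copy number, a
multi-trait quantitative phenotype matrix with SNP effects planted in
functional clusters, and survival times with cause-of-death categories.

Every planted effect is recorded in the cohort's truth ledger so downstream
estimators can be validated against known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterSpec",
    "ArtifactSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_probe_intensities",
    "simulate_read_counts",
    "simulate_qpcr_plates",
    "write_cohort_tsv",
    "write_minimal_vcf",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class ClusterSpec:
    """One functional cluster of SNPs sharing a trait-effect template.

    Member SNPs all affect copy number (``mtcn_beta``, per allele on the
    standardized latent scale) and affect each trait ``t`` with coefficient
    ``template[t] * mtcn_beta`` — i.e. trait effects are proportional to the
    copy-number effect, which is exactly the structure the scaled-beta
    clustering stage assumes.
    """

    cluster_id: int
    snps: tuple[int, ...]
    template: tuple[float, ...]
    mtcn_beta: float = 0.08


@dataclass(frozen=True)
class ArtifactSpec:
    """Technical-artifact magnitudes for the assay simulators."""

    batch_shift: float = 0.5        # mean intensity offset between arrays
    probe_noise_sd: float = 0.1     # per-probe intensity noise
    plate_sd: float = 0.3           # qPCR plate random-intercept sd
    pipetting_slope: float = 0.01   # ΔCt drift per well position
    ct_noise_sd: float = 0.05       # per-replicate Ct noise


def _default_clusters(n_snps: int, n_traits: int) -> tuple[ClusterSpec, ...]:
    """Three clusters of 20 SNPs each, with effects on disjoint trait blocks."""
    if n_snps < 60 or n_traits < 9:
        return ()
    templates = []
    for c in range(3):
        t = np.zeros(n_traits)
        t[3 * c: 3 * c + 3] = [1.0, -0.8, 0.6]
        templates.append(tuple(t))
    return tuple(
        ClusterSpec(
            cluster_id=c,
            snps=tuple(range(20 * c, 20 * c + 20)),
            template=templates[c],
        )
        for c in range(3)
    )


@dataclass
class SimulationConfig:
    n_individuals: int = 2000
    n_snps: int = 500
    n_mtsnps: int = 120
    ld_block_size: int = 20
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 41
    n_cell_types: int = 5
    cluster_spec: tuple[ClusterSpec, ...] | None = None
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    # copy-number model
    confound_weight: float = 0.3    # shared factor → latent copy number
    noise_sd: float = 0.8           # residual sd of the latent copy number
    mtcn_baseline: float = 100.0    # multiplicative centre of true_mtcn
    mtcn_log_scale: float = 0.25    # log true_mtcn = log(base) + scale·latent
    # traits
    trait_mtcn_loading: float = 0.15  # direct mtDNA-CN → trait loading
    trait_noise_sd: float = 1.0
    # mitochondrial haplotype structure
    n_backbones: int = 8
    backbone_mutation_rate: float = 0.002
    mito_hap_trait_beta: float = 0.0   # planted backbone effect on trait 0
    # survival
    followup_days: float = 3650.0
    baseline_hazard: float = 2e-5     # per day → ~7% event rate over follow-up
    hap_log_hr: float = 0.0           # planted log-HR for backbone 1 carriers
    cause_probs: tuple[float, float, float] = (0.05, 0.40, 0.55)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} outside (0, 0.5]")
        for name in ("n_individuals", "n_snps", "n_mtsnps", "n_traits",
                     "ld_block_size", "n_cell_types", "n_backbones"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.mtcn_baseline <= 0:
            raise ConfigurationError("mtcn_baseline must be positive")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the ledger of every planted effect."""

    individuals: pd.Index
    nuclear_genotypes: pd.DataFrame    # individuals × SNPs, dosages {0,1,2}
    snp_positions: pd.DataFrame        # id, chrom, pos, genotyped flag
    mito_genotypes: pd.DataFrame       # individuals × mtSNPs, alleles {0,1}
    mito_meta: pd.DataFrame            # mtSNP id, genotyped_ukbb/ukbl flags
    mito_backbone: np.ndarray          # backbone index per individual
    array_batch: pd.Series             # {"UKBB", "UKBL"}
    true_mtcn: pd.Series               # latent copy number, positive
    latent: pd.Series                  # standardized latent driving true_mtcn
    covariates: pd.DataFrame           # age, sex, center
    cell_counts: pd.DataFrame          # individuals × K cell types
    traits: pd.DataFrame               # individuals × T
    survival: pd.DataFrame             # time, event, cause
    truth: pd.DataFrame                # ledger: snp, trait, beta
    config: SimulationConfig


def _simulate_ld_genotypes(rng: np.random.Generator, n: int, n_snps: int,
                           block: int, rho: float,
                           mafs: np.ndarray) -> np.ndarray:
    """Diploid dosages with blockwise AR(1) LD via a Gaussian copula.

    Two latent haplotypes per individual; within a block the latent variables
    have corr(i, j) = rho^|i-j|; a haplotype carries the alternate allele when
    its latent value falls below the MAF quantile, so HWE holds marginally.
    """
    thresholds = stats.norm.ppf(mafs)
    dosage = np.zeros((n, n_snps), dtype=np.int8)
    for start in range(0, n_snps, block):
        stop = min(start + block, n_snps)
        m = stop - start
        # AR(1) generated sequentially: z_j = rho z_{j-1} + sqrt(1-rho²) e_j
        for _hap in range(2):
            z = np.empty((n, m))
            z[:, 0] = rng.standard_normal(n)
            innov = rng.standard_normal((n, m))
            s = np.sqrt(1.0 - rho * rho)
            for j in range(1, m):
                z[:, j] = rho * z[:, j - 1] + s * innov[:, j]
            dosage[:, start:stop] += (z < thresholds[start:stop]).astype(np.int8)
    return dosage


def _simulate_mito(rng: np.random.Generator, n: int, n_mtsnps: int,
                   n_backbones: int, mutation_rate: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Haploid mitochondrial genotypes from mutated haplotype backbones."""
    backbones = rng.binomial(1, 0.3, size=(n_backbones, n_mtsnps)).astype(np.int8)
    # skewed backbone frequencies, like real haplogroup distributions
    freqs = np.sort(rng.dirichlet(np.full(n_backbones, 2.0)))[::-1]
    assignment = rng.choice(n_backbones, size=n, p=freqs)
    geno = backbones[assignment].copy()
    flips = rng.random((n, n_mtsnps)) < mutation_rate
    geno[flips] = 1 - geno[flips]
    return geno, assignment


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    individuals = pd.Index([f"IND{i:06d}" for i in range(n)], name="iid")

    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    dosage = _simulate_ld_genotypes(rng, n, config.n_snps,
                                    config.ld_block_size, config.ld_rho, mafs)
    snp_ids = [f"rs{100000 + i}" for i in range(config.n_snps)]
    nuclear = pd.DataFrame(dosage, index=individuals, columns=snp_ids)
    # SNPs spaced 5 kb apart on one synthetic chromosome; ~60% genotyped
    snp_positions = pd.DataFrame({
        "id": snp_ids,
        "chrom": "1",
        "pos": 1 + 5000 * np.arange(config.n_snps),
        "genotyped": rng.random(config.n_snps) < 0.6,
        "maf": mafs,
    })

    mito, backbone = _simulate_mito(rng, n, config.n_mtsnps,
                                    config.n_backbones,
                                    config.backbone_mutation_rate)
    mt_ids = [f"MT{50 + 110 * i}" for i in range(config.n_mtsnps)]
    mito_genotypes = pd.DataFrame(mito, index=individuals, columns=mt_ids)
    mito_meta = pd.DataFrame({
        "id": mt_ids,
        "genotyped_ukbb": rng.random(config.n_mtsnps) < 0.7,
        "genotyped_ukbl": rng.random(config.n_mtsnps) < 0.7,
    })

    batch = pd.Series(np.where(rng.random(n) < 0.9, "UKBB", "UKBL"),
                      index=individuals, name="array_batch")

    covariates = pd.DataFrame({
        "age": rng.uniform(40, 70, n).round(1),
        "sex": rng.integers(0, 2, n),
        "center": rng.integers(0, 5, n),
    }, index=individuals)

    # shared latent factor confounds copy number and the first two cell types
    shared = rng.standard_normal(n)
    k = config.n_cell_types
    cells = rng.standard_normal((n, k))
    cells[:, 0] += 0.8 * shared
    cells[:, 1] += 0.6 * shared
    cell_counts = pd.DataFrame(
        cells, index=individuals,
        columns=[f"cell_{j}" for j in range(k)])

    clusters = (config.cluster_spec if config.cluster_spec is not None
                else _default_clusters(config.n_snps, config.n_traits))

    beta_mtcn = np.zeros(config.n_snps)
    truth_rows: list[dict] = []
    for cl in clusters:
        for s in cl.snps:
            beta_mtcn[s] = cl.mtcn_beta
            truth_rows.append({"snp": snp_ids[s], "trait": "mtcn",
                               "beta": cl.mtcn_beta, "cluster": cl.cluster_id})

    genetic = dosage @ beta_mtcn
    latent = (genetic + config.confound_weight * shared
              + config.noise_sd * rng.standard_normal(n))
    true_mtcn = config.mtcn_baseline * np.exp(config.mtcn_log_scale * latent)
    latent_s = pd.Series(latent, index=individuals, name="latent")
    true_mtcn_s = pd.Series(true_mtcn, index=individuals, name="true_mtcn")

    # traits: direct mtDNA-CN loading + cluster-template SNP effects + noise
    t_count = config.n_traits
    trait_mat = (config.trait_mtcn_loading * latent[:, None]
                 * np.ones((1, t_count))
                 + config.trait_noise_sd * rng.standard_normal((n, t_count)))
    age_c = covariates["age"].to_numpy() - covariates["age"].mean()
    trait_mat += 0.02 * age_c[:, None]     # mild age effect, removable by covariates
    for cl in clusters:
        template = np.asarray(cl.template)
        for s in cl.snps:
            eff = template * beta_mtcn[s]
            trait_mat += np.outer(dosage[:, s], eff)
            for t in np.nonzero(eff)[0]:
                truth_rows.append({"snp": snp_ids[s], "trait": f"trait_{t}",
                                   "beta": eff[t], "cluster": cl.cluster_id})
    if config.mito_hap_trait_beta != 0.0:
        trait_mat[:, 0] += config.mito_hap_trait_beta * (backbone == 1)
        truth_rows.append({"snp": "backbone_1", "trait": "trait_0",
                           "beta": config.mito_hap_trait_beta, "cluster": -1})
    traits = pd.DataFrame(trait_mat, index=individuals,
                          columns=[f"trait_{t}" for t in range(t_count)])

    # survival: exponential event times under proportional hazards
    log_hr = config.hap_log_hr * (backbone == 1)
    rate = config.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / rate)
    time = np.minimum(event_time, config.followup_days)
    event = (event_time <= config.followup_days).astype(int)
    cause = np.full(n, "censored", dtype=object)
    causes = rng.choice(["external", "cancer", "non_cancer"], size=n,
                        p=config.cause_probs)
    cause[event == 1] = causes[event == 1]
    if config.hap_log_hr != 0.0:
        truth_rows.append({"snp": "backbone_1", "trait": "log_hr",
                           "beta": config.hap_log_hr, "cluster": -1})
    survival = pd.DataFrame({"time": time, "event": event, "cause": cause},
                            index=individuals)

    truth = pd.DataFrame(truth_rows,
                         columns=["snp", "trait", "beta", "cluster"])
    return SyntheticCohort(
        individuals=individuals, nuclear_genotypes=nuclear,
        snp_positions=snp_positions, mito_genotypes=mito_genotypes,
        mito_meta=mito_meta, mito_backbone=backbone, array_batch=batch,
        true_mtcn=true_mtcn_s, latent=latent_s, covariates=covariates,
        cell_counts=cell_counts, traits=traits, survival=survival,
        truth=truth, config=config,
    )


def simulate_probe_intensities(
    cohort: SyntheticCohort,
    artifact_spec: ArtifactSpec | None = None,
    n_nuclear_probes: int = 100,
    signal_scale: float = 1.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Array probe intensities carrying a log copy-number signal.

    Mitochondrial probe intensity for sample *i*, probe *p* is
    ``signal_scale·log(true_mtcn_i) + batch shift + noise``; nuclear probes
    carry the same technical components but no copy-number signal.  A
    homozygosity mask marks the mitochondrial probes usable by the
    median-intensity estimator.

    Returns ``(mt_intensities, homozygous_mask, nuclear_intensities)``.
    """
    spec = artifact_spec if artifact_spec is not None else cohort.config.artifact_spec
    rng = np.random.default_rng(
        cohort.config.seed + 1 if seed is None else seed)
    n = len(cohort.individuals)
    n_mt = cohort.mito_genotypes.shape[1]

    batch_off = np.where(cohort.array_batch.to_numpy() == "UKBB",
                         0.0, spec.batch_shift)
    signal = signal_scale * np.log(cohort.true_mtcn.to_numpy())
    mt = (signal[:, None] + batch_off[:, None]
          + spec.probe_noise_sd * rng.standard_normal((n, n_mt)))
    mt_df = pd.DataFrame(mt, index=cohort.individuals,
                         columns=cohort.mito_genotypes.columns)

    mask = rng.random((n, n_mt)) < 0.9
    mask_df = pd.DataFrame(mask, index=cohort.individuals,
                           columns=cohort.mito_genotypes.columns)

    nuc = (batch_off[:, None]
           + spec.probe_noise_sd * rng.standard_normal((n, n_nuclear_probes)))
    nuc_df = pd.DataFrame(nuc, index=cohort.individuals,
                          columns=[f"nucprobe_{j}" for j in range(n_nuclear_probes)])
    return mt_df, mask_df, nuc_df


def simulate_read_counts(
    cohort: SyntheticCohort,
    mean_total_reads: float = 5e5,
    mt_fraction_per_copy: float = 2e-6,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sequencing read counts with mt reads proportional to copy number.

    Total aligned reads are Poisson around ``mean_total_reads``; mitochondrial
    reads are Poisson with expectation
    ``total · mt_fraction_per_copy · true_mtcn``.
    """
    if mean_total_reads <= 0:
        raise ConfigurationError("mean_total_reads must be positive")
    rng = np.random.default_rng(
        cohort.config.seed + 2 if seed is None else seed)
    n = len(cohort.individuals)
    total = rng.poisson(mean_total_reads, size=n)
    lam = total * mt_fraction_per_copy * cohort.true_mtcn.to_numpy()
    mt_reads = rng.poisson(lam)
    return pd.DataFrame({"mt_reads": mt_reads, "total_reads": total},
                        index=cohort.individuals)


def simulate_qpcr_plates(
    cohort: SyntheticCohort,
    plate_size: int = 90,
    n_replicates: int = 3,
    n_calibrators: int = 3,
    artifact_spec: ArtifactSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Triplicate qPCR Ct values on plates with order and plate artifacts.

    ΔCt = mt_Ct − nuclear_Ct carries −log2(true_mtcn), a plate random
    intercept, and a linear pipetting-order trend.  Three calibrator wells
    (aliquots of one reference sample) are added to every plate to support
    per-plate calibration.  Long format: one row per (sample, replicate).
    """
    if plate_size < 1:
        raise ConfigurationError("plate_size must be >= 1")
    spec = artifact_spec if artifact_spec is not None else cohort.config.artifact_spec
    rng = np.random.default_rng(
        cohort.config.seed + 3 if seed is None else seed)
    n = len(cohort.individuals)
    iids = list(cohort.individuals)
    signal = -np.log2(cohort.true_mtcn.to_numpy())  # ΔCt falls as mtcn rises
    cal_signal = -np.log2(cohort.config.mtcn_baseline)

    rows = []
    n_plates = int(np.ceil(n / plate_size))
    plate_re = spec.plate_sd * rng.standard_normal(n_plates)
    for p in range(n_plates):
        members = iids[p * plate_size:(p + 1) * plate_size]
        wells: list[tuple[str, bool, float]] = [
            (iid, False, signal[p * plate_size + j])
            for j, iid in enumerate(members)
        ]
        wells += [(f"CAL{c}", True, cal_signal) for c in range(n_calibrators)]
        order = 0
        for iid, is_cal, sig in wells:
            for rep in range(n_replicates):
                order += 1
                nuc_ct = 25.0 + spec.ct_noise_sd * rng.standard_normal()
                dct = (10.0 + sig + plate_re[p]
                       + spec.pipetting_slope * order
                       + spec.ct_noise_sd * rng.standard_normal())
                rows.append({
                    "sample_id": iid, "plate": f"P{p:03d}", "order": order,
                    "replicate": rep, "mt_ct": nuc_ct + dct,
                    "nuclear_ct": nuc_ct, "is_calibrator": is_cal,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers

def write_cohort_tsv(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write genotypes, traits, covariates, cell counts and the truth ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("nuclear_genotypes", cohort.nuclear_genotypes),
        ("mito_genotypes", cohort.mito_genotypes),
        ("traits", cohort.traits),
        ("covariates", cohort.covariates),
        ("cell_counts", cohort.cell_counts),
        ("snp_positions", cohort.snp_positions),
        ("survival", cohort.survival),
        ("truth", cohort.truth),
    ]:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=name not in ("snp_positions", "truth"))
        paths[name] = p
    return paths


def write_minimal_vcf(cohort: SyntheticCohort, path: str | Path) -> Path:
    """Minimal uncompressed VCF (GT only) for the nuclear genotypes."""
    path = Path(path)
    iids = list(cohort.individuals)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(iids) + "\n")
        dosage = cohort.nuclear_genotypes.to_numpy()
        for j, row in cohort.snp_positions.iterrows():
            gts = "\t".join(gt_map[int(d)] for d in dosage[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\tA\tG\t.\t.\t.\tGT\t{gts}\n")
    return path
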