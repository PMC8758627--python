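"""Mitochondrial variant association, haplotypes, and cause-specific survival.

Mitochondrial SNPs are haploid, so each variant is tested by linear
regression of trait on allele within genotyping-array strata (with MAF and
imputation-INFO filters applied per stratum) and combined by fixed-effect
inverse-variance weighting.  Study-wide significance is calibrated with
normally distributed dummy traits: the rank-15 smallest of 300 per-trait
minimum p-values, divided by the number of real tests.  Haplotypes are built
by concatenating, across credible sets, the highest-PIP member SNP that is
directly genotyped on both arrays; rare haplotypes (frequency < 0.005) are
set missing and the most common is the reference.  Trait association uses an
F-test between nested regressions with and without haplotype indicators;
mortality uses Cox proportional hazards with cause-specific censoring
(external causes always censored; the competing cause censored per mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .assoc import single_variant_assoc, ivw_meta
from .finemap import CredibleSet

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeTable",
    "with_age_squared",
    "mtsnp_scan",
    "dummy_trait_threshold",
    "build_haplotypes",
    "haplotype_anova",
    "cox_mortality",
    "prune_independent_snps",
]


@dataclass
class HaplotypeTable:
    """Per-individual mitochondrial haplotype labels after rare masking."""

    labels: pd.Series              # concatenated allele string, NaN if rare
    frequencies: pd.Series         # over non-missing individuals, sums to 1
    reference: str                 # most common haplotype
    snps: list[str]                # one selected SNP per credible set
    n_masked: int                  # individuals set missing by the MAF floor

    def __post_init__(self) -> None:
        if len(self.frequencies) and abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("haplotype frequencies must sum to 1")


def with_age_squared(covariates: pd.DataFrame) -> pd.DataFrame:
    """Covariates plus a centered age² term (age kept as-is)."""
    out = covariates.copy()
    age_c = out["age"] - out["age"].mean()
    out["age_sq"] = age_c ** 2
    return out


def _drop_collinear(cov: pd.DataFrame) -> pd.DataFrame:
    keep: list[str] = []
    n = len(cov)
    for c in cov.columns:
        trial = np.column_stack(
            [np.ones(n)] + [cov[k].to_numpy(dtype=float) for k in keep + [c]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(c)
        else:
            logger.warning("covariate %r collinear; dropped", c)
    return cov[keep]


def mtsnp_scan(
    mito_genotypes: pd.DataFrame,
    traits: pd.DataFrame,
    covariates: pd.DataFrame,
    strata: pd.Series,
    info: pd.DataFrame | None = None,
    maf_min: float = 0.005,
    info_min: float = 0.80,
) -> pd.DataFrame:
    """Array-stratified mtSNP association with IVW meta-analysis.

    One row per (SNP, trait) that passes the per-stratum MAF and INFO
    filters in at least one stratum.  ``info`` is an optional stratum × SNP
    table of imputation quality (default 1.0).
    """
    cov = _drop_collinear(covariates)
    stratum_names = sorted(strata.unique())
    per_stratum: dict[str, dict[str, pd.DataFrame]] = {}
    maf_ok: dict[str, pd.Series] = {}
    for s in stratum_names:
        rows = strata.index[strata == s]
        G = mito_genotypes.loc[rows]
        af = G.mean(axis=0)
        maf = np.minimum(af, 1.0 - af)
        ok = maf > maf_min
        if info is not None and s in info.index:
            ok &= info.loc[s].reindex(G.columns).fillna(1.0) > info_min
        maf_ok[s] = ok
        per_stratum[s] = {}
        G_ok = G.loc[:, ok[ok].index]
        for t in traits.columns:
            res = single_variant_assoc(G_ok, traits[t].loc[rows], cov.loc[rows])
            res["maf"] = maf.loc[ok].to_numpy()
            per_stratum[s][t] = res.set_index("id")

    records = []
    for snp in mito_genotypes.columns:
        for t in traits.columns:
            strata_rows = []
            for s in stratum_names:
                if not maf_ok[s].get(snp, False):
                    continue
                r = per_stratum[s][t].loc[snp]
                if np.isfinite(r["beta"]) and np.isfinite(r["se"]):
                    row = r.copy()
                    row["id"] = snp
                    strata_rows.append(row)
            if not strata_rows:
                continue
            meta = ivw_meta(strata_rows)
            records.append({
                "snp": snp, "trait": t, "beta": meta["beta"],
                "se": meta["se"], "p": meta["p"], "n": meta["n"],
                "n_strata": len(strata_rows),
            })
    return pd.DataFrame(records)


def dummy_trait_threshold(
    mito_genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    strata: pd.Series,
    n_dummy: int = 300,
    rank: int = 15,
    n_traits: int = 42,
    rng: np.random.Generator | None = None,
    maf_min: float = 0.005,
) -> tuple[float, np.ndarray]:
    """Study-wide p threshold from normally distributed dummy traits.

    For each of ``n_dummy`` N(0,1) traits the stratified scan is run and the
    minimum p recorded; the threshold is the rank-th smallest minimum
    divided by ``n_traits`` (the real traits plus the copy-number metric).
    Returns (threshold, the n_dummy minima).
    """
    if n_dummy < rank:
        raise ValueError("n_dummy must be >= rank")
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    n = len(mito_genotypes)
    dummies = pd.DataFrame(
        rng.standard_normal((n, n_dummy)), index=mito_genotypes.index,
        columns=[f"dummy_{b}" for b in range(n_dummy)])
    scan = mtsnp_scan(mito_genotypes, dummies, covariates, strata,
                      maf_min=maf_min)
    minima = scan.groupby("trait")["p"].min().to_numpy()
    threshold = float(np.sort(minima)[rank - 1] / n_traits)
    return threshold, minima


def build_haplotypes(
    mito_genotypes: pd.DataFrame,
    credible_sets: list[CredibleSet],
    genotyped_both_mask: pd.Series,
    maf_floor: float = 0.005,
) -> HaplotypeTable:
    """Concatenated-allele haplotypes from one SNP per credible set.

    From each credible set the highest-PIP member genotyped on both arrays
    is taken (substituting down the PIP order when the top SNP fails the
    mask).  Haplotypes rarer than ``maf_floor`` are set missing; the most
    common haplotype is the reference.
    """
    chosen: list[str] = []
    for cs in credible_sets:
        pick = None
        for v in cs.variants:  # already sorted by descending PIP
            if bool(genotyped_both_mask.get(v, False)):
                pick = v
                break
        if pick is None:
            raise ValueError(
                f"credible set {cs.locus_id!r} has no member genotyped on both arrays")
        if pick != cs.variants[0]:
            logger.info("credible set %s: %s substituted for top-PIP %s",
                        cs.locus_id, pick, cs.variants[0])
        chosen.append(pick)

    alleles = mito_genotypes[chosen].astype(int).astype(str)
    labels = alleles.agg("".join, axis=1)
    freq = labels.value_counts(normalize=True)
    rare = freq.index[freq < maf_floor]
    masked = labels.isin(rare)
    labels = labels.where(~masked)
    n_masked = int(masked.sum())
    freq_final = labels.value_counts(normalize=True)
    reference = freq_final.idxmax()
    return HaplotypeTable(labels=labels, frequencies=freq_final,
                          reference=reference, snps=chosen, n_masked=n_masked)


def _haplotype_design(haplotypes: HaplotypeTable,
                      min_carriers: int = 2) -> pd.DataFrame:
    """Indicator columns for non-reference haplotype levels."""
    labels = haplotypes.labels.copy()
    counts = labels.value_counts()
    tiny = counts.index[counts < min_carriers]
    if len(tiny):
        logger.warning("haplotype levels with < %d carriers set missing: %s",
                       min_carriers, list(tiny))
        labels = labels.where(~labels.isin(tiny))
    levels = [h for h in labels.dropna().unique() if h != haplotypes.reference]
    if not levels:
        raise ValueError("only the reference haplotype present; test undefined")
    ind = pd.DataFrame({f"hap_{h}": (labels == h).astype(float) for h in sorted(levels)},
                       index=labels.index)
    ind[labels.isna()] = np.nan
    return ind


def haplotype_anova(
    trait: pd.Series,
    haplotypes: HaplotypeTable,
    covariates: pd.DataFrame,
) -> tuple[float, pd.DataFrame]:
    """F-test between regressions with and without haplotype indicators.

    Returns (p-value, per-haplotype effects vs the reference).
    """
    ind = _haplotype_design(haplotypes)
    df = pd.concat([trait.rename("y"), ind, covariates], axis=1).dropna()
    y = df["y"].to_numpy()
    hap_cols = list(ind.columns)
    X_red = sm.add_constant(df[covariates.columns].to_numpy(dtype=float))
    X_full = np.column_stack([X_red, df[hap_cols].to_numpy(dtype=float)])
    fit_red = sm.OLS(y, X_red).fit()
    fit_full = sm.OLS(y, X_full).fit()
    q = len(hap_cols)
    dof = fit_full.df_resid
    f_stat = ((fit_red.ssr - fit_full.ssr) / q) / (fit_full.ssr / dof)
    p = float(sps.f.sf(f_stat, q, dof))
    k = X_red.shape[1]
    effects = pd.DataFrame({
        "haplotype": [c.removeprefix("hap_") for c in hap_cols],
        "beta": fit_full.params[k:],
        "se": fit_full.bse[k:],
    })
    return p, effects


def cox_mortality(
    haplotypes: HaplotypeTable,
    survival: pd.DataFrame,
    covariates: pd.DataFrame,
    mode: str = "all",
) -> dict:
    """Cause-specific Cox proportional hazards with haplotype indicators.

    ``mode``: ``all`` (any non-external death is an event), ``cancer``
    (non-cancer deaths censored), ``non_cancer`` (cancer deaths censored);
    external-cause deaths are always censored at the death time.  Returns a
    dict with hazard ratios, the likelihood-ratio global p for the
    haplotype block, and the event count.
    """
    if mode not in ("all", "cancer", "non_cancer"):
        raise ValueError(f"unknown mode {mode!r}")
    event_causes = {"all": {"cancer", "non_cancer"},
                    "cancer": {"cancer"},
                    "non_cancer": {"non_cancer"}}[mode]
    event = (survival["event"].astype(bool)
             & survival["cause"].isin(event_causes)).astype(int)
    if event.sum() == 0:
        raise ValueError(f"no events remain after {mode!r} censoring")

    ind = _haplotype_design(haplotypes)
    df = pd.concat([survival["time"].rename("time"), event.rename("event"),
                    ind, covariates], axis=1).dropna()
    from lifelines import CoxPHFitter
    hap_cols = list(ind.columns)
    full = CoxPHFitter()
    full.fit(df, duration_col="time", event_col="event")
    red_df = df.drop(columns=hap_cols)
    if red_df.shape[1] > 2:
        reduced = CoxPHFitter()
        reduced.fit(red_df, duration_col="time", event_col="event")
        ll_red = reduced.log_likelihood_
    else:  # covariate-free null model
        ll_red = _null_cox_loglik(red_df["time"].to_numpy(),
                                  red_df["event"].to_numpy())
    lr = 2.0 * (full.log_likelihood_ - ll_red)
    global_p = float(sps.chi2.sf(max(lr, 0.0), df=len(hap_cols)))
    hr = np.exp(full.params_[hap_cols])
    return {
        "hazard_ratios": hr,
        "log_hr": full.params_[hap_cols],
        "se": full.standard_errors_[hap_cols],
        "global_p": global_p,
        "n_events": int(df["event"].sum()),
        "mode": mode,
        "model": full,
    }


def _null_cox_loglik(time: np.ndarray, event: np.ndarray) -> float:
    """Partial log-likelihood of the no-covariate Cox model (Breslow)."""
    event_times = time[event.astype(bool)]
    n_risk = (time[None, :] >= event_times[:, None]).sum(axis=1)
    return float(-np.log(n_risk).sum())


def prune_independent_snps(
    genotypes: pd.DataFrame,
    traits: pd.DataFrame,
    snps: list[str],
    p_keep: float = 5e-4,
) -> list[str]:
    """Iterative multivariate pruning of credible-set SNPs.

    All SNPs enter one multivariate regression per trait; a SNP stays only
    while its best (smallest) p across traits is below ``p_keep``.  The
    worst SNP is removed and the fit repeated until all survivors qualify.
    """
    current = list(snps)
    while current:
        min_p = pd.Series(np.inf, index=current)
        X = sm.add_constant(genotypes[current].to_numpy(dtype=float))
        for t in traits.columns:
            fit = sm.OLS(traits[t].to_numpy(), X).fit()
            min_p = np.minimum(min_p, pd.Series(fit.pvalues[1:], index=current))
        worst = min_p.idxmax()
        if min_p[worst] < p_keep:
            break
        current.remove(worst)
    return current
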