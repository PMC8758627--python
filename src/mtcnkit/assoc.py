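"""Per-variant association, IVW meta-analysis, inflation, and locus rules.

Single-variant tests are ordinary least squares with covariates, computed by
the Frisch–Waugh–Lovell decomposition so a whole genotype matrix is scanned
in one vectorized pass.  Strata are combined by fixed-effect inverse-variance
weighting.  Loci are identified greedily: the most significant genome-wide
significant (GWS, p < 5e-8) SNP claims a 1 Mb window (lead ± 500 kb) and is
retained only when the window holds at least two GWS SNPs or the lead is
directly genotyped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ASSOC_COLUMNS",
    "Locus",
    "single_variant_assoc",
    "ivw_meta",
    "genomic_inflation",
    "identify_loci",
    "conditional_scan",
    "loci_shared",
    "proportion_concordance_test",
    "expected_nominal",
    "GWS_THRESHOLD",
]

GWS_THRESHOLD = 5e-8
CHI2_1_MEDIAN = sps.chi2.ppf(0.5, df=1)  # 0.4549...

ASSOC_COLUMNS = ["id", "chrom", "pos", "ea", "oa",
                 "beta", "se", "p", "n", "maf", "info"]


@dataclass
class Locus:
    """A lead SNP and its 1 Mb window of genome-wide significant SNPs."""

    lead: str
    chrom: str
    lead_pos: int
    start: int
    end: int
    lead_p: float
    n_gws: int
    retained: bool
    retention_reason: str | None  # "two_gws" | "genotyped_lead" | None
    members: list[str] = field(default_factory=list)
    secondary_leads: list[str] = field(default_factory=list)


def _residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the column space of X."""
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


def single_variant_assoc(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    variant_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Linear-regression association of every variant with a phenotype.

    Rows of ``genotypes`` (individuals × variants, dosages) must align with
    ``phenotype`` and ``covariates``.  Monomorphic variants get missing beta.
    ``variant_meta`` may supply id/chrom/pos/ea/oa/info columns indexed by
    variant id; otherwise placeholders are emitted.
    """
    idx = phenotype.dropna().index
    G = genotypes.loc[idx].to_numpy(dtype=float)
    y = phenotype.loc[idx].to_numpy(dtype=float)
    n, m = G.shape
    if covariates is not None and covariates.shape[1] > 0:
        X = np.column_stack([np.ones(n),
                             covariates.loc[idx].to_numpy(dtype=float)])
    else:
        X = np.ones((n, 1))
    k = X.shape[1]

    Gr = _residualize(G, X)
    yr = _residualize(y[:, None], X)[:, 0]

    gss = (Gr ** 2).sum(axis=0)
    mono = gss < 1e-12
    gss_safe = np.where(mono, np.nan, gss)
    beta = (Gr * yr[:, None]).sum(axis=0) / gss_safe
    dof = n - k - 1
    rss = (yr ** 2).sum() - beta ** 2 * gss_safe
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / gss_safe)
    tval = beta / se
    p = 2.0 * sps.t.sf(np.abs(tval), dof)
    if mono.any():
        logger.warning("%d monomorphic variants emitted with missing beta",
                       int(mono.sum()))

    af = G.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    out = pd.DataFrame({
        "id": genotypes.columns,
        "chrom": "1", "pos": np.arange(m), "ea": "G", "oa": "A",
        "beta": beta, "se": se, "p": p, "n": n, "maf": maf, "info": 1.0,
    })
    if variant_meta is not None:
        meta = variant_meta.set_index("id") if "id" in variant_meta.columns else variant_meta
        for col in ("chrom", "pos", "ea", "oa", "info", "maf"):
            if col in meta.columns:
                out[col] = out["id"].map(meta[col]).fillna(out[col])
    return out


def ivw_meta(stats: list[pd.Series] | pd.DataFrame) -> pd.Series:
    """Fixed-effect inverse-variance-weighted meta-analysis of one variant.

    Strata whose effect allele is the other stratum's other allele have their
    beta sign flipped before combining; strata whose alleles neither match
    nor swap raise ``ValueError``.
    """
    if isinstance(stats, pd.DataFrame):
        rows = [stats.iloc[i] for i in range(len(stats))]
    else:
        rows = list(stats)
    if not rows:
        raise ValueError("no strata to meta-analyze")
    ref = rows[0]
    betas, ws = [], []
    n_total = 0
    for r in rows:
        beta = float(r["beta"])
        if (r["ea"], r["oa"]) == (ref["ea"], ref["oa"]):
            pass
        elif (r["ea"], r["oa"]) == (ref["oa"], ref["ea"]):
            beta = -beta
        else:
            raise ValueError(
                f"irreconcilable alleles {r['ea']}/{r['oa']} vs {ref['ea']}/{ref['oa']}")
        se = float(r["se"])
        if se <= 0:
            raise ValueError("standard errors must be positive")
        betas.append(beta)
        ws.append(1.0 / se ** 2)
        n_total += int(r.get("n", 0))
    ws = np.asarray(ws)
    betas = np.asarray(betas)
    beta_meta = float((ws * betas).sum() / ws.sum())
    se_meta = float(1.0 / np.sqrt(ws.sum()))
    z = beta_meta / se_meta
    p = float(2.0 * sps.norm.sf(abs(z)))
    return pd.Series({
        "id": ref["id"], "chrom": ref.get("chrom", "1"),
        "pos": ref.get("pos", np.nan), "ea": ref["ea"], "oa": ref["oa"],
        "beta": beta_meta, "se": se_meta, "p": p, "n": n_total,
        "maf": ref.get("maf", np.nan), "info": ref.get("info", np.nan),
    })


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor λ: median χ²(1) of the tests / null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = sps.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def identify_loci(
    stats: pd.DataFrame,
    gws_threshold: float = GWS_THRESHOLD,
    window: int = 1_000_000,
    genotyped_set: set[str] | None = None,
) -> list[Locus]:
    """Greedy 1 Mb-window locus identification with retention rules.

    Repeatedly selects the most significant remaining GWS SNP (ties broken by
    smaller position, then id), assigns every GWS SNP within ± window/2 to
    its locus, and marks the locus retained when the window holds ≥ 2 GWS
    SNPs or the lead is directly genotyped.  Output is independent of input
    row order.
    """
    genotyped_set = genotyped_set or set()
    half = window // 2
    gws = stats[stats["p"] < gws_threshold].copy()
    gws = gws.sort_values(["p", "pos", "id"]).reset_index(drop=True)
    loci: list[Locus] = []
    remaining = gws
    while len(remaining):
        lead = remaining.iloc[0]
        same_chrom = remaining["chrom"] == lead["chrom"]
        in_window = same_chrom & (remaining["pos"] - lead["pos"]).abs().le(half)
        members = remaining[in_window]
        n_gws = len(members)
        if n_gws >= 2:
            retained, reason = True, "two_gws"
        elif lead["id"] in genotyped_set:
            retained, reason = True, "genotyped_lead"
        else:
            retained, reason = False, None
        loci.append(Locus(
            lead=lead["id"], chrom=str(lead["chrom"]),
            lead_pos=int(lead["pos"]),
            start=int(lead["pos"]) - half, end=int(lead["pos"]) + half,
            lead_p=float(lead["p"]), n_gws=n_gws, retained=retained,
            retention_reason=reason, members=list(members["id"]),
        ))
        remaining = remaining[~in_window]
    return loci


def conditional_scan(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None,
    lead_snps: list[str],
    gws_threshold: float = GWS_THRESHOLD,
    variant_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Re-scan with lead-SNP dosages as extra covariates.

    Returns the association table restricted to newly genome-wide-significant
    variants (the leads themselves excluded).  Lead SNPs collinear with the
    covariates are dropped with a warning.
    """
    lead_df = genotypes[ [s for s in lead_snps if s in genotypes.columns] ]
    base = (covariates.copy() if covariates is not None
            else pd.DataFrame(index=genotypes.index))
    for s in lead_df.columns:
        trial = pd.concat([base, lead_df[[s]]], axis=1).to_numpy(dtype=float)
        trial = np.column_stack([np.ones(len(trial)), trial])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            base[s] = lead_df[s]
        else:
            logger.warning("lead SNP %r collinear with covariates; dropped", s)
    res = single_variant_assoc(genotypes, phenotype, base, variant_meta)
    res = res[~res["id"].isin(lead_snps)]
    return res[res["p"] < gws_threshold].reset_index(drop=True)


def proportion_concordance_test(k: int, n: int, p0: float = 0.5) -> float:
    """One-sided normal-approximation test of a concordance proportion.

    Tests whether k of n direction-of-effect agreements exceed chance
    (``p0``), with no continuity correction: z = (k/n − p0)/√(p0(1−p0)/n).
    Used for cross-ancestry sign concordance of lead-SNP effects.
    """
    if not (0 < n and 0 <= k <= n):
        raise ValueError("need 0 <= k <= n, n > 0")
    z = (k / n - p0) / np.sqrt(p0 * (1 - p0) / n)
    return float(sps.norm.sf(z))


def expected_nominal(n_tests: int, alpha: float = 0.05) -> float:
    """Expected count of nominally significant tests under the global null."""
    return n_tests * alpha


def loci_shared(pos_a: int, pos_b: int, max_distance: int = 500_000) -> bool:
    """Whether two lead SNPs mark the same locus across GWASs.

    True when the leads are fewer than ``max_distance`` base pairs apart.
    """
    return abs(int(pos_a) - int(pos_b)) < max_distance
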