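"""Credible sets, final-lead selection, ABF colocalization, gene assignment.

Fine-mapping output (posterior inclusion probabilities, PIPs) is consumed as
tables; a Wakefield approximate-Bayes-factor single-effect fine-mapper is
provided as the built-in stand-in for synthetic tests.  Colocalization
follows the standard ABF framework — per-SNP log Bayes factors for each
trait, summed over the five causal configurations H0–H4 — with two
robustness modifications: rescaling of extreme z-scores whose p-values
underflow, and a rerun after dropping the single SNP with the smallest
combined p-value when one overwhelming SNP masks a shared secondary signal.
Genes are assigned to loci by a fixed evidence hierarchy: missense variant
inside the credible set, colocalization (PP4), co-regulation evidence, then
nearest gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "CredibleSet",
    "ColocResult",
    "GeneAssignment",
    "wakefield_abf",
    "credible_set_from_pips",
    "select_final_lead",
    "coloc_abf",
    "rescale_extreme_z",
    "coloc_drop_top_snp",
    "assign_gene",
]


@dataclass
class CredibleSet:
    """A coverage-level credible set with per-SNP PIPs, sorted descending."""

    locus_id: str
    variants: list[str]
    pips: list[float]
    coverage: float = 0.95
    purity: float | None = None     # min |r| among members, when LD known
    complete: bool = True           # False when total PIP < coverage

    def __post_init__(self) -> None:
        if any(p < 0 or p > 1 for p in self.pips):
            raise ValueError("PIPs must lie in [0, 1]")
        order = np.argsort(self.pips)[::-1]
        self.variants = [self.variants[i] for i in order]
        self.pips = [self.pips[i] for i in order]


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    locus_id: str
    gene_id: str
    pp: tuple[float, float, float, float, float]  # PP0..PP4
    n_snps: int
    dropped_variant: str | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.pp) - 1.0) > 1e-8 or any(p < 0 for p in self.pp):
            raise ValueError("PP0..PP4 must be nonnegative and sum to 1")

    @property
    def pp4(self) -> float:
        return self.pp[4]


@dataclass
class GeneAssignment:
    """Gene(s) assigned to a locus with the evidence tier that fired."""

    locus_id: str
    genes: list[str]
    tier: str  # missense_in_cs | coloc | depict | nearest | unassigned
    support: dict[str, float] = field(default_factory=dict)


def wakefield_abf(beta: float, se: float, prior_sd_w: float = 0.15) -> float:
    """Log approximate Bayes factor (alternative over null) for one SNP.

    Shrinkage form: with z = beta/se and r = W²/(se² + W²),
    log ABF = 0.5·log(1 − r) + 0.5·z²·r.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd_w <= 0:
        raise ValueError("prior_sd_w must be positive")
    z = beta / se
    r = prior_sd_w ** 2 / (se ** 2 + prior_sd_w ** 2)
    out = 0.5 * np.log(1.0 - r) + 0.5 * z ** 2 * r
    return float(out) if out.ndim == 0 else out


def credible_set_from_pips(pips: pd.Series, coverage: float = 0.95,
                           locus_id: str = "locus") -> CredibleSet:
    """Smallest set of descending-PIP variants whose PIPs sum to coverage.

    When total PIP falls short of the coverage level, the full set is
    returned flagged incomplete.
    """
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    s = pips.sort_values(ascending=False, kind="mergesort")
    csum = s.cumsum()
    if csum.iloc[-1] < coverage:
        logger.warning("total PIP %.3f below coverage %.2f; returning full set",
                       csum.iloc[-1], coverage)
        return CredibleSet(locus_id, list(s.index), list(s.to_numpy()),
                           coverage, complete=False)
    k = int(np.searchsorted(csum.to_numpy(), coverage) + 1)
    return CredibleSet(locus_id, list(s.index[:k]), list(s.iloc[:k]), coverage)


def select_final_lead(initial_lead: str, credible_set: CredibleSet,
                      pip_gate: float = 0.2, ratio_gate: float = 1.75) -> str:
    """Replace the GWAS lead by the top-PIP SNP only under strong evidence.

    The top-PIP SNP is returned iff its PIP exceeds ``pip_gate`` and is at
    least ``ratio_gate`` times the second-highest PIP; otherwise the
    initially identified lead is kept.  Idempotent.
    """
    if not credible_set.variants:
        raise ValueError("credible set is empty")
    top = credible_set.pips[0]
    second = credible_set.pips[1] if len(credible_set.pips) > 1 else 0.0
    if top > pip_gate and top >= ratio_gate * second:
        return credible_set.variants[0]
    return initial_lead


def _abf_per_snp(stats: pd.DataFrame, prior_sd_w: float) -> pd.Series:
    ok = stats.dropna(subset=["beta", "se"])
    dropped = len(stats) - len(ok)
    if dropped:
        logger.warning("%d variants dropped for missing beta/se", dropped)
    labf = wakefield_abf(ok["beta"].to_numpy(), ok["se"].to_numpy(), prior_sd_w)
    return pd.Series(labf, index=ok["id"].to_numpy())


def coloc_abf(
    gwas_stats: pd.DataFrame,
    eqtl_stats: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd_w: float = 0.15,
    locus_id: str = "locus",
    gene_id: str = "gene",
) -> ColocResult:
    """ABF colocalization of a GWAS signal with one gene's eQTL signal.

    Both tables need id/beta/se columns; only shared variants are used
    (≥ 2 required).  Priors p1/p2/p12 are the per-SNP prior probabilities of
    a trait-1-only, trait-2-only, and shared causal variant.
    """
    l1 = _abf_per_snp(gwas_stats, prior_sd_w)
    l2 = _abf_per_snp(eqtl_stats, prior_sd_w)
    shared = l1.index.intersection(l2.index)
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared variants; need >= 2")
    a = l1.loc[shared].to_numpy()
    b = l2.loc[shared].to_numpy()

    s1 = logsumexp(a)
    s2 = logsumexp(b)
    s12 = logsumexp(a + b)
    # sum over distinct causal SNP pairs: exp(s1)·exp(s2) − exp(s12)
    both = np.add.outer(a, b)
    np.fill_diagonal(both, -np.inf)
    s3 = logsumexp(both)

    logs = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + s3,
        np.log(p12) + s12,
    ])
    pp = np.exp(logs - logsumexp(logs))
    pp = pp / pp.sum()
    return ColocResult(locus_id, gene_id, tuple(pp), n_snps=len(shared))


def rescale_extreme_z(z_scores, cap: float = 37.02,
                      floor_p: float = 5e-300) -> np.ndarray:
    """P-values from z-scores, rescaled when the largest would underflow.

    If max |z| exceeds ``cap``, every z is multiplied by the constant that
    maps the largest |z| onto the two-sided p-value ``floor_p``; rank order
    is preserved.  Otherwise p-values are computed directly.
    """
    z = np.asarray(z_scores, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    zmax = np.abs(z).max() if z.size else 0.0
    if zmax > cap:
        target = sps.norm.isf(floor_p / 2.0)
        z = z * (target / zmax)
    return 2.0 * sps.norm.sf(np.abs(z))


def coloc_drop_top_snp(
    gwas_stats: pd.DataFrame,
    eqtl_stats: pd.DataFrame,
    **coloc_kwargs,
) -> ColocResult:
    """Colocalization after removing the single most dominant shared SNP.

    The SNP minimizing (GWAS p + eQTL p) over shared variants is removed and
    the analysis rerun; ties are broken by smaller position when available,
    else by id.  Guards against one overwhelming SNP (e.g. from an LD
    mismatch between panels) masking a genuinely shared secondary signal.
    """
    g = gwas_stats.set_index("id")
    e = eqtl_stats.set_index("id")
    shared = g.index.intersection(e.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared variants to drop one")
    combined = g.loc[shared, "p"] + e.loc[shared, "p"]
    lowest = combined.min()
    tied = combined.index[combined == lowest]
    if len(tied) > 1:
        logger.warning("tie for lowest combined p among %s", list(tied))
        if "pos" in g.columns:
            drop = g.loc[tied, "pos"].astype(int).idxmin()
        else:
            drop = sorted(tied)[0]
    else:
        drop = tied[0]
    res = coloc_abf(gwas_stats[gwas_stats["id"] != drop],
                    eqtl_stats[eqtl_stats["id"] != drop], **coloc_kwargs)
    res.dropped_variant = drop
    return res


def assign_gene(
    locus_id: str,
    final_lead_pos: int,
    credible_set_variants: list[str],
    missense_table: pd.DataFrame | None,
    coloc_results: list[ColocResult],
    depict_results: pd.DataFrame | None,
    gene_positions: pd.DataFrame,
    pp4_cutoff: float = 0.50,
    pp4_tie_margin: float = 0.05,
    depict_alpha: float = 0.05,
    max_nearest_distance: int = 1_000_000,
) -> GeneAssignment:
    """Tiered gene assignment for one locus.

    Tier 1: gene(s) with a missense variant inside the credible set.
    Tier 2: top colocalized gene with PP4 > ``pp4_cutoff``; any other gene
    with PP4 within ``pp4_tie_margin`` (absolute) is co-assigned.
    Tier 3: most significant co-regulation (DEPICT-style) gene at nominal
    p < ``depict_alpha``.
    Tier 4: nearest gene to the final lead within ``max_nearest_distance``.
    Exactly one tier fires.
    """
    if missense_table is not None and len(missense_table):
        hits = missense_table[
            missense_table["variant"].isin(credible_set_variants)
            & (missense_table["consequence"] == "missense")]
        if len(hits):
            genes = sorted(hits["gene"].unique())
            return GeneAssignment(locus_id, genes, "missense_in_cs")

    if coloc_results:
        best = max(coloc_results, key=lambda r: r.pp4)
        if best.pp4 > pp4_cutoff:
            genes = sorted({r.gene_id for r in coloc_results
                            if best.pp4 - r.pp4 <= pp4_tie_margin})
            support = {r.gene_id: r.pp4 for r in coloc_results
                       if r.gene_id in genes}
            return GeneAssignment(locus_id, genes, "coloc", support)

    if depict_results is not None and len(depict_results):
        sig = depict_results[depict_results["p"] < depict_alpha]
        if len(sig):
            top = sig.loc[sig["p"].idxmin()]
            return GeneAssignment(locus_id, [top["gene"]], "depict",
                                  {top["gene"]: float(top["p"])})

    gp = gene_positions.copy()
    dist = np.minimum(np.abs(gp["start"] - final_lead_pos),
                      np.abs(gp["end"] - final_lead_pos))
    dist[(gp["start"] <= final_lead_pos) & (final_lead_pos <= gp["end"])] = 0
    gp["dist"] = dist
    gp = gp[gp["dist"] <= max_nearest_distance]
    if not len(gp):
        logger.warning("locus %s: no gene within %d bp; unassigned",
                       locus_id, max_nearest_distance)
        return GeneAssignment(locus_id, [], "unassigned")
    nearest = gp.loc[gp["dist"].idxmin()]
    return GeneAssignment(locus_id, [nearest["gene"]], "nearest",
                          {nearest["gene"]: float(nearest["dist"])})
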