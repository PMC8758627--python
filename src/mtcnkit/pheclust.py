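"""PHEWAS scan, scaled-beta matrix, UMAP+DBSCAN clustering, enrichment.

Genome-wide significant mtDNA-CN SNPs are profiled across quantitative
traits; each SNP–trait beta is divided by that SNP's mtDNA-CN beta so all
effects are oriented to the copy-number-increasing allele and scaled to the
copy-number effect.  The scaled matrix is embedded in two dimensions with
UMAP and grouped with DBSCAN.  Phenotype enrichment within a cluster
compares the in-cluster median scaled beta to the out-of-cluster median,
with significance from label permutations; the family-wise threshold comes
from outer permutations of the cluster assignment, keeping the most
significant result of each and taking the rank-⌈αN⌉ value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import single_variant_assoc

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterConfig",
    "ScaledBetaMatrix",
    "EnrichmentResult",
    "phewas_scan",
    "age_spline_covariates",
    "snp_trait_betas",
    "build_scaled_matrix",
    "embed_and_cluster",
    "dbscan_knee_eps",
    "cluster_enrichment",
    "enrichment_scan",
    "studywide_threshold",
]


@dataclass
class ClusterConfig:
    """UMAP and DBSCAN settings for the SNP-clustering stage."""

    n_neighbors: int = 10
    min_dist: float = 0.001
    n_components: int = 2
    n_epochs: int = 200
    random_state: int = 123
    min_pts: int = 10
    eps: float | None = None  # None → knee-of-kNN-distance heuristic

    def __post_init__(self) -> None:
        if self.n_components < 2 or self.min_pts < 2:
            raise ValueError("n_components >= 2 and min_pts >= 2 required")


@dataclass
class ScaledBetaMatrix:
    """SNP × trait matrix of trait betas scaled by each SNP's mtDNA-CN beta."""

    matrix: pd.DataFrame
    mtcn_beta: pd.Series

    def __post_init__(self) -> None:
        if self.matrix.isna().any().any():
            raise ValueError("scaled matrix must be complete after filtering")


@dataclass
class EnrichmentResult:
    cluster_id: int
    phenotype: str
    median_in: float
    median_out: float
    observed: float       # |median_in - median_out|
    p: float
    n_perm: int
    studywide_significant: bool | None = None


def phewas_scan(
    mtcn_adjusted: pd.Series,
    traits: pd.DataFrame,
    covariates: pd.DataFrame,
    selection_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-trait association of the adjusted copy-number metric.

    Each quantitative trait is regressed on the metric with covariates
    (age, sex, assessment center).  Constant traits are skipped.  Traits
    with p below ``selection_threshold`` (default Bonferroni 0.05/T) are
    flagged for downstream SNP-trait profiling.
    """
    idx = mtcn_adjusted.dropna().index
    x = mtcn_adjusted.loc[idx].to_numpy()
    C = np.column_stack([np.ones(len(idx)),
                         covariates.loc[idx].to_numpy(dtype=float)])
    coef, *_ = np.linalg.lstsq(C, x, rcond=None)
    xr = x - C @ coef

    keep = [c for c in traits.columns if traits[c].loc[idx].std() > 0]
    skipped = set(traits.columns) - set(keep)
    if skipped:
        logger.warning("constant traits skipped: %s", sorted(skipped))
    Y = traits[keep].loc[idx].to_numpy(dtype=float)
    coefs, *_ = np.linalg.lstsq(C, Y, rcond=None)
    Yr = Y - C @ coefs

    xss = (xr ** 2).sum()
    beta = Yr.T @ xr / xss
    dof = len(idx) - C.shape[1] - 1
    rss = (Yr ** 2).sum(axis=0) - beta ** 2 * xss
    se = np.sqrt(rss / dof / xss)
    from scipy import stats as sps
    p = 2.0 * sps.t.sf(np.abs(beta / se), dof)
    if selection_threshold is None:
        selection_threshold = 0.05 / len(keep)
    return pd.DataFrame({"trait": keep, "beta": beta, "se": se, "p": p,
                         "selected": p < selection_threshold})


def natural_spline_basis(x: np.ndarray, df: int = 2) -> np.ndarray:
    """Natural cubic spline basis (df columns, intercept excluded).

    Knots sit at df+1 uniform quantiles of ``x``; the basis is the classic
    truncated-power construction with linearity enforced beyond the boundary
    knots: N1(x) = x, N_{k+1}(x) = d_k(x) − d_{K−1}(x) with
    d_k(x) = [(x−ξ_k)³₊ − (x−ξ_K)³₊] / (ξ_K − ξ_k).
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return x[:, None]
    knots = np.quantile(x, np.linspace(0, 1, df + 1))
    if len(np.unique(knots)) < len(knots):
        raise ValueError("degenerate age distribution: duplicate spline knots")
    K = len(knots)

    def d(k):
        return (np.clip(x - knots[k], 0, None) ** 3
                - np.clip(x - knots[K - 1], 0, None) ** 3) / (knots[K - 1] - knots[k])

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


def age_spline_covariates(covariates: pd.DataFrame, df: int = 2) -> pd.DataFrame:
    """Covariates with age replaced by a natural cubic spline basis (df=2)."""
    basis = natural_spline_basis(covariates["age"].to_numpy(), df=df)
    out = covariates.drop(columns=["age"]).copy()
    for j in range(basis.shape[1]):
        out[f"age_ns{j + 1}"] = basis[:, j]
    return out


def snp_trait_betas(
    genotypes: pd.DataFrame,
    traits: pd.DataFrame,
    covariates: pd.DataFrame,
    spline_age_df: int | None = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP × trait effect estimates with the PHEWAS covariate structure.

    Each trait is regressed on each SNP dosage adjusting for sex, a natural
    spline on age (default df 2) and the remaining covariates.  Returns
    (beta, se) DataFrames indexed by SNP id.
    """
    cov = covariates
    if spline_age_df is not None and "age" in covariates.columns:
        cov = age_spline_covariates(covariates, df=spline_age_df)
    betas, ses = {}, {}
    for t in traits.columns:
        res = single_variant_assoc(genotypes, traits[t], cov)
        betas[t] = res.set_index("id")["beta"]
        ses[t] = res.set_index("id")["se"]
    return pd.DataFrame(betas), pd.DataFrame(ses)


def build_scaled_matrix(
    snp_trait_beta: pd.DataFrame,
    snp_mtcn_stats: pd.DataFrame,
    beta_floor: float = 1e-6,
) -> ScaledBetaMatrix:
    """Divide every SNP's trait betas by its mtDNA-CN beta.

    The ratio is invariant to effect-allele orientation since flipping the
    allele flips numerator and denominator together.  SNPs whose copy-number
    beta is below ``beta_floor`` in magnitude are excluded.
    """
    mtcn_beta = snp_mtcn_stats.set_index("id")["beta"]
    snps = snp_trait_beta.index.intersection(mtcn_beta.index)
    if len(snps) < len(snp_trait_beta):
        missing = set(snp_trait_beta.index) - set(snps)
        raise ValueError(f"SNPs missing mtDNA-CN stats: {sorted(missing)[:5]}")
    mb = mtcn_beta.loc[snps]
    small = mb.abs() < beta_floor
    if small.any():
        logger.warning("excluding %d SNPs with |mtDNA-CN beta| < %g",
                       int(small.sum()), beta_floor)
    keep = snps[~small]
    scaled = snp_trait_beta.loc[keep].div(mb.loc[keep], axis=0)
    return ScaledBetaMatrix(matrix=scaled, mtcn_beta=mb.loc[keep])


def dbscan_knee_eps(X: np.ndarray, min_pts: int) -> float:
    """Knee of the sorted min_pts-nearest-neighbor distance curve.

    The knee is the point of maximum distance to the chord joining the
    curve's endpoints — a standard eps heuristic for DBSCAN.
    """
    from sklearn.neighbors import NearestNeighbors
    k = min(min_pts, len(X) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    curve = np.sort(dist[:, -1])
    n = len(curve)
    if n < 3 or curve[-1] == curve[0]:
        return float(curve[-1] if n else 1.0) or 1.0
    t = np.arange(n) / (n - 1)
    chord = curve[0] + t * (curve[-1] - curve[0])
    knee = int(np.argmax(np.abs(curve - chord)))
    eps = float(curve[knee])
    return eps if eps > 0 else float(curve[-1])


def embed_and_cluster(
    matrix: ScaledBetaMatrix,
    config: ClusterConfig | None = None,
    robustness_grid: list[dict] | None = None,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame | None]:
    """UMAP embedding plus DBSCAN labels (−1 = noise).

    Returns (labels, embedding, robustness report).  The robustness report —
    cluster labels recomputed across a grid of n_neighbors / min_dist /
    random_state values — is produced when ``robustness_grid`` is given.
    """
    import umap
    from sklearn.cluster import DBSCAN

    config = config or ClusterConfig()
    X = matrix.matrix.to_numpy(dtype=float)
    n = len(X)
    if n < config.min_pts:
        logger.warning("fewer SNPs (%d) than minPts (%d): all noise",
                       n, config.min_pts)
        labels = pd.Series(-1, index=matrix.matrix.index, name="cluster")
        emb = pd.DataFrame(np.zeros((n, config.n_components)),
                           index=matrix.matrix.index)
        return labels, emb, None

    def run(n_neighbors, min_dist, random_state):
        reducer = umap.UMAP(
            n_neighbors=min(n_neighbors, n - 1), min_dist=min_dist,
            n_components=config.n_components, n_epochs=config.n_epochs,
            random_state=random_state)
        emb = reducer.fit_transform(X)
        eps = config.eps if config.eps is not None else dbscan_knee_eps(emb, config.min_pts)
        lab = DBSCAN(eps=eps, min_samples=config.min_pts).fit_predict(emb)
        return emb, lab, eps

    emb, lab, eps = run(config.n_neighbors, config.min_dist, config.random_state)
    logger.info("DBSCAN eps=%.4g, clusters=%d", eps, len(set(lab) - {-1}))
    labels = pd.Series(lab, index=matrix.matrix.index, name="cluster")
    embedding = pd.DataFrame(
        emb, index=matrix.matrix.index,
        columns=[f"UMAP{j + 1}" for j in range(config.n_components)])

    report = None
    if robustness_grid:
        rows = {}
        for params in robustness_grid:
            key = "nn{n_neighbors}_md{min_dist}_rs{random_state}".format(**params)
            _, lab_g, _ = run(**params)
            rows[key] = lab_g
        report = pd.DataFrame(rows, index=matrix.matrix.index)
    return labels, embedding, report


def _perm_stats(values: np.ndarray, m: int, n_perm: int,
                rng: np.random.Generator) -> np.ndarray:
    """|median_in − median_out| for n_perm random size-m clusters.

    Returns an (n_perm, T) array; fully vectorized over permutations.
    """
    n = values.shape[0]
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    med_in = np.median(values[order[:, :m]], axis=1)
    med_out = np.median(values[order[:, m:]], axis=1)
    return np.abs(med_in - med_out)


def cluster_enrichment(
    matrix: ScaledBetaMatrix,
    labels: pd.Series,
    cluster_id: int,
    n_perm: int = 20_000,
    rng: np.random.Generator | None = None,
) -> list[EnrichmentResult]:
    """Permutation enrichment of every phenotype within one cluster.

    Statistic: |in-cluster median scaled beta − out-of-cluster median|.
    The null permutes cluster membership over SNPs; p uses the add-one
    estimator (1 + #{null ≥ observed}) / (1 + n_perm), so p ≥ 1/(n_perm+1).
    """
    rng = rng if rng is not None else np.random.default_rng()
    values = matrix.matrix.to_numpy(dtype=float)
    mask = (labels.loc[matrix.matrix.index] == cluster_id).to_numpy()
    m = int(mask.sum())
    if m < 2 or (len(mask) - m) < 2:
        raise ValueError(f"cluster {cluster_id} untestable: {m} members, "
                         f"{len(mask) - m} non-members")
    med_in = np.median(values[mask], axis=0)
    med_out = np.median(values[~mask], axis=0)
    observed = np.abs(med_in - med_out)
    null = _perm_stats(values, m, n_perm, rng)
    p = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (1.0 + n_perm)
    return [
        EnrichmentResult(cluster_id, t, float(med_in[j]), float(med_out[j]),
                         float(observed[j]), float(p[j]), n_perm)
        for j, t in enumerate(matrix.matrix.columns)
    ]


def enrichment_scan(
    matrix: ScaledBetaMatrix,
    labels: pd.Series,
    n_perm: int = 20_000,
    rng: np.random.Generator | None = None,
) -> list[EnrichmentResult]:
    """Enrichment of every phenotype in every non-noise cluster."""
    rng = rng if rng is not None else np.random.default_rng()
    results: list[EnrichmentResult] = []
    for c in sorted(set(labels) - {-1}):
        results.extend(cluster_enrichment(matrix, labels, c, n_perm, rng))
    return results


def studywide_threshold(
    matrix: ScaledBetaMatrix,
    labels: pd.Series,
    n_outer: int = 300,
    rank: int | None = None,
    n_perm_inner: int = 20_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Family-wise p threshold from outer permutations of cluster labels.

    Each outer round shuffles the cluster assignment, recomputes every
    cluster × phenotype enrichment p-value, and keeps the minimum; the
    threshold is the rank-th smallest of the ``n_outer`` minima, where rank
    defaults to ⌈0.05·n_outer⌉ (15 for 300).  Returns (threshold, minima).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if rank is None:
        rank = math.ceil(0.05 * n_outer)
    if n_outer < rank:
        raise ValueError("n_outer must be >= rank")
    lab = labels.loc[matrix.matrix.index].to_numpy()
    minima = np.empty(n_outer)
    for b in range(n_outer):
        perm_lab = pd.Series(rng.permutation(lab), index=matrix.matrix.index)
        res = enrichment_scan(matrix, perm_lab, n_perm=n_perm_inner, rng=rng)
        minima[b] = min(r.p for r in res)
    threshold = float(np.sort(minima)[rank - 1])
    return threshold, minima
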