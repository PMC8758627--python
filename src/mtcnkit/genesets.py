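"""Resampling-robust gene-set enrichment and depletion-gene Fisher test.

Loci frequently carry several candidate genes that are functionally related,
so enrichment run on all of them would double-count single signals.  The
procedure here draws one gene per locus (uniformly among a locus's assigned
genes, prioritizing primary hits), computes per-term hypergeometric
enrichment against an annotation table, and calibrates the significance
cutoff by re-running the same enrichment on random gene draws of matched
size (cutoff = 5th percentile of the null minimum p distribution).  The draw
is repeated 50 times and only terms passing the cutoff in at least 40 of 50
iterations are retained.  A one-sided Fisher's exact test checks whether the
assigned genes are enriched for genes known to cause mtDNA depletion
syndromes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .finemap import GeneAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DEPLETION_GENES",
    "GeneSetRun",
    "hypergeom_term_enrichment",
    "one_per_locus_sample",
    "permutation_cutoff",
    "robust_terms",
    "fisher_set_enrichment",
]

# Package-curated default list of genes causal for mtDNA depletion syndromes
# (replaceable by the user's own list at call time).
DEFAULT_DEPLETION_GENES: tuple[str, ...] = (
    "TK2", "DGUOK", "POLG", "POLG2", "TWNK", "SUCLA2", "SUCLG1", "RRM2B",
    "TYMP", "MPV17", "OPA1", "MGME1", "FBXL4", "AGK", "SLC25A4", "TFAM",
)


@dataclass
class GeneSetRun:
    """One resampling iteration: the drawn gene list and its term results."""

    iteration: int
    genes: list[str]
    term_p: pd.Series
    cutoff: float
    passing_terms: list[str]


def hypergeom_term_enrichment(
    genes: Sequence[str],
    annotation: pd.DataFrame,
    universe: Sequence[str] | None = None,
) -> pd.Series:
    """One-sided hypergeometric enrichment p per annotation term.

    ``annotation`` maps terms to genes (columns ``term``, ``gene``); the
    universe defaults to every gene appearing in the annotation.
    """
    if universe is None:
        universe = annotation["gene"].unique()
    universe = pd.Index(universe).unique()
    n_universe = len(universe)
    if n_universe == 0:
        raise ValueError("empty gene universe")
    genes = pd.Index(genes).unique().intersection(universe)
    n_drawn = len(genes)
    term_sizes = annotation.groupby("term")["gene"].nunique()
    overlap = (annotation[annotation["gene"].isin(genes)]
               .groupby("term")["gene"].nunique()
               .reindex(term_sizes.index, fill_value=0))
    p = sps.hypergeom.sf(overlap - 1, n_universe, term_sizes, n_drawn)
    return pd.Series(p, index=term_sizes.index, name="p")


def one_per_locus_sample(
    assignments: Sequence[GeneAssignment],
    rng: np.random.Generator,
    primary_loci: set[str] | None = None,
) -> list[str]:
    """Draw one gene per locus, uniformly among each locus's assigned genes.

    When a locus appears in several assignments (e.g. primary and secondary
    independent hits), genes from assignments whose locus id is in
    ``primary_loci`` are preferred.  Loci with no genes are skipped with a
    warning.  Single-gene loci contribute their gene deterministically.
    """
    by_locus: dict[str, list[str]] = {}
    primary_by_locus: dict[str, list[str]] = {}
    for a in assignments:
        by_locus.setdefault(a.locus_id, []).extend(a.genes)
        if primary_loci and a.locus_id in primary_loci:
            primary_by_locus.setdefault(a.locus_id, []).extend(a.genes)
    out: list[str] = []
    for locus in by_locus:
        candidates = primary_by_locus.get(locus) or by_locus[locus]
        candidates = sorted(set(candidates))
        if not candidates:
            logger.warning("locus %s has no assigned genes; skipped", locus)
            continue
        if len(candidates) == 1:
            out.append(candidates[0])
        else:
            out.append(candidates[rng.integers(len(candidates))])
    return out


def permutation_cutoff(
    universe: Sequence[str],
    k: int,
    enrichment_fn: Callable[[Sequence[str]], pd.Series],
    n_perm: int = 1000,
    percentile: float = 5.0,
    rng: np.random.Generator | None = None,
) -> float:
    """P-value cutoff from the null distribution of minimum term p-values.

    ``k`` random genes (matching the analyzed list's size) are drawn from
    the universe ``n_perm`` times; the cutoff is the ``percentile``-th
    percentile of the per-draw minimum p.  A failing draw is retried once,
    then skipped with a log entry.
    """
    rng = rng if rng is not None else np.random.default_rng()
    universe = list(pd.Index(universe).unique())
    if k > len(universe):
        raise ValueError("k exceeds the size of the gene universe")
    minima = []
    for _ in range(n_perm):
        for attempt in range(2):
            draw = [universe[i] for i in rng.choice(len(universe), size=k,
                                                    replace=False)]
            try:
                minima.append(float(enrichment_fn(draw).min()))
                break
            except Exception as exc:  # pragma: no cover - defensive
                if attempt:
                    logger.warning("enrichment failed twice on a draw: %s", exc)
    if not minima:
        raise RuntimeError("every permutation draw failed")
    return float(np.percentile(minima, percentile))


def robust_terms(
    assignments: Sequence[GeneAssignment],
    annotation: pd.DataFrame,
    n_iter: int = 50,
    retain_min: int = 40,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    primary_loci: set[str] | None = None,
    universe: Sequence[str] | None = None,
) -> tuple[pd.Series, list[GeneSetRun]]:
    """Terms passing permutation cutoffs in ≥ retain_min of n_iter draws.

    Each iteration draws one gene per locus, computes per-term enrichment,
    derives a matched-size permutation cutoff, and records the passing
    terms.  Returns (pass counts for retained terms, all iteration records).
    Invariant to the ordering of the input assignments.
    """
    if n_iter < retain_min:
        raise ValueError("n_iter must be >= retain_min")
    rng = rng if rng is not None else np.random.default_rng()
    assignments = sorted(assignments, key=lambda a: a.locus_id)
    if universe is None:
        universe = annotation["gene"].unique()

    def enr(genes):
        return hypergeom_term_enrichment(genes, annotation, universe)

    counts: dict[str, int] = {}
    runs: list[GeneSetRun] = []
    for it in range(n_iter):
        genes = one_per_locus_sample(assignments, rng, primary_loci)
        term_p = enr(genes)
        cutoff = permutation_cutoff(universe, len(set(genes)), enr,
                                    n_perm=n_perm, rng=rng)
        passing = list(term_p.index[term_p <= cutoff])
        for t in passing:
            counts[t] = counts.get(t, 0) + 1
        runs.append(GeneSetRun(it, genes, term_p, cutoff, passing))
    pass_counts = pd.Series(counts, dtype=int).sort_values(ascending=False)
    retained = pass_counts[pass_counts >= retain_min]
    return retained, runs


def fisher_set_enrichment(
    selected_genes: Sequence[str],
    target_set: Sequence[str] = DEFAULT_DEPLETION_GENES,
    universe: Sequence[str] | None = None,
) -> tuple[float, np.ndarray]:
    """One-sided Fisher's exact test for overlap with a target gene set.

    Tests whether ``selected_genes`` overlap ``target_set`` more than chance
    within ``universe`` (default: union of both lists is rejected — a proper
    universe must be supplied unless target ∪ selected covers it).  Returns
    (upper-tail p, 2×2 contingency table) for audit.
    """
    if universe is None:
        raise ValueError("a gene universe must be supplied")
    universe_ix = pd.Index(universe).unique()
    if len(universe_ix) == 0:
        raise ValueError("empty gene universe")
    selected = pd.Index(selected_genes).unique().intersection(universe_ix)
    target = pd.Index(target_set).unique().intersection(universe_ix)
    a = len(selected.intersection(target))
    b = len(selected) - a
    c = len(target) - a
    d = len(universe_ix) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = sps.fisher_exact(table, alternative="greater")
    return float(p), table
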