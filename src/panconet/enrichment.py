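"""Fisher's exact test enrichment of modules against gene-set collections.

One-sided hypergeometric upper-tail p-values with Benjamini-Hochberg
correction per (module x collection) family; a hit is significant when the
overlap exceeds three genes and the adjusted p-value (aFETP) is below 0.05.
Cytoband enrichment reuses the same machinery with each band's gene content
as one set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("panconet")


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        clean = {}
        for sid, genes in self.sets.items():
            inside = set(genes) & self.universe
            if len(inside) < len(genes):
                logger.debug("collection %s set %s: %d genes outside the "
                             "universe dropped", self.name, sid,
                             len(genes) - len(inside))
            if inside:
                clean[sid] = inside
        self.sets = clean


@dataclass
class EnrichmentResult:
    module_id: str
    set_id: str
    overlap: int          # k
    module_size: int      # m (within universe)
    set_size: int         # s
    universe_size: int    # N
    p: float
    adj_p: float = np.nan
    significant: bool = False
    overlap_genes: frozenset = field(default_factory=frozenset)


def hypergeom_tail(k: int, N: int, s: int, m: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, s, m)."""
    return float(hypergeom.sf(k - 1, N, s, m))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(module: set[str], collection: GeneSetCollection,
                      module_id: str = "module",
                      size_bounds: tuple[int, int] = (10, 500),
                      min_overlap: int = 4, alpha: float = 0.05,
                      ) -> list[EnrichmentResult]:
    """Test one module against every set in a collection.

    The module is intersected with the universe first; modules outside
    ``size_bounds`` are skipped (empty result, logged). BH correction is
    applied across the collection's sets for this module. Significance
    requires overlap >= min_overlap (i.e. "greater than three") and
    aFETP < alpha.
    """
    m_genes = set(module) & collection.universe
    if not m_genes:
        raise ValueError(f"module {module_id} shares no genes with the "
                         f"universe of collection {collection.name}")
    m = len(m_genes)
    lo, hi = size_bounds
    if not lo <= m <= hi:
        logger.info("module %s size %d outside [%d, %d]; enrichment skipped",
                    module_id, m, lo, hi)
        return []
    N = len(collection.universe)
    results = []
    for sid in sorted(collection.sets):
        genes = collection.sets[sid]
        k = len(m_genes & genes)
        p = hypergeom_tail(k, N, len(genes), m)
        results.append(EnrichmentResult(module_id, sid, k, m, len(genes), N,
                                        p, overlap_genes=frozenset(
                                            m_genes & genes)))
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.adj_p = float(a)
        r.significant = bool(r.overlap >= min_overlap and a < alpha)
    return results


def enrich_hierarchy(hierarchy, collection: GeneSetCollection,
                     size_bounds: tuple[int, int] = (10, 500),
                     min_overlap: int = 4, alpha: float = 0.05,
                     skip_root: bool = True) -> pd.DataFrame:
    """Run fisher_enrichment for every eligible module of a hierarchy."""
    rows = []
    for mod in hierarchy.modules:
        if skip_root and mod.parent is None:
            continue
        if not size_bounds[0] <= len(mod.genes) <= size_bounds[1]:
            continue
        try:
            results = fisher_enrichment(set(mod.genes), collection, mod.id,
                                        size_bounds, min_overlap, alpha)
        except ValueError:
            continue
        rows.extend({"module_id": r.module_id, "set_id": r.set_id,
                     "overlap": r.overlap, "module_size": r.module_size,
                     "set_size": r.set_size, "universe_size": r.universe_size,
                     "p": r.p, "adj_p": r.adj_p,
                     "significant": r.significant} for r in results)
    return pd.DataFrame(rows, columns=["module_id", "set_id", "overlap",
                                       "module_size", "set_size",
                                       "universe_size", "p", "adj_p",
                                       "significant"])


def cytoband_collection(gene_annotation: pd.DataFrame,
                        universe: set[str] | None = None) -> GeneSetCollection:
    """Build a gene-set collection whose sets are cytoband gene contents."""
    ann = gene_annotation.dropna(subset=["cytoband"])
    if ann.empty:
        raise ValueError("no annotated genes")
    sets = {band: set(sub.index)
            for band, sub in ann.groupby("cytoband", sort=True)}
    if universe is None:
        universe = set(ann.index)
    return GeneSetCollection("cytoband", sets, universe)


def cytoband_enrichment(hierarchy, gene_annotation: pd.DataFrame,
                        universe: set[str] | None = None,
                        size_bounds: tuple[int, int] = (10, 500),
                        min_overlap: int = 4,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Fisher enrichment of every eligible module against cytoband windows."""
    coll = cytoband_collection(gene_annotation, universe)
    return enrich_hierarchy(hierarchy, coll, size_bounds, min_overlap, alpha)
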