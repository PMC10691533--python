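"""Planar filtered coexpression networks and their multiscale module hierarchy.

The construction follows the planar-maximally-filtered-graph recipe: all
pairwise Pearson correlations are computed, a permutation-based FDR estimate
picks the |r| cutoff, surviving pairs are sorted by |r| and greedily inserted
into a growing graph whenever the insertion preserves planarity. The planar
network is then recursively partitioned by maximizing Newman's modularity Q,
giving a hierarchy of nested modules at multiple scales, and hub genes are
flagged by comparing node connectivity against label-permuted planar nulls.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("panconet")


# ------------------------------------------------------------ correlations

def pairwise_correlation(matrix: pd.DataFrame,
                         min_shared: int = 10) -> np.ndarray:
    """Pearson correlation matrix across genes (rows).

    Fully observed matrices use the fast path; with missing values,
    pairwise-complete correlations are computed and pairs sharing fewer than
    ``min_shared`` samples are set to NaN (excluded downstream).
    """
    Y = matrix.to_numpy(dtype=float)
    if Y.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    if not np.isnan(Y).any():
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(Y)
        return np.atleast_2d(R)
    R = matrix.T.corr(min_periods=min_shared).to_numpy()
    return R


def _upper(R: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(R.shape[0], k=1)
    return R[iu]


@dataclass
class CorrelationThresholdResult:
    """Permutation-FDR scan over candidate |r| cutoffs."""
    cutoffs: np.ndarray                 # candidate |r| grid
    observed_counts: np.ndarray         # pairs with |r| >= cutoff, real data
    permuted_counts: np.ndarray         # mean over permutations
    fdr: np.ndarray                     # permuted / observed per cutoff
    chosen_cutoff: float
    n_permutations: int
    pairs: pd.DataFrame = field(repr=False)  # gene_a, gene_b, abs_r, r


def permutation_fdr_threshold(matrix: pd.DataFrame, n_perm: int = 10,
                              alpha: float = 0.05, seed: int | None = 0,
                              grid_step: float = 0.01,
                              ) -> CorrelationThresholdResult:
    """Choose the smallest |r| cutoff with permutation-estimated FDR <= alpha.

    Each gene row is independently permuted across samples (n_perm times,
    preserving gene marginals); for every cutoff c on the grid the FDR is the
    mean permuted count of pairs with |r| >= c divided by the observed count
    (0/0 -> 0, k/0 -> inf). Returns the scan plus the ranked significant pair
    list at the chosen cutoff (ties in |r| broken by lexicographic gene pair).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    genes = matrix.index.to_numpy()
    R = pairwise_correlation(matrix)
    obs = np.abs(_upper(R))
    obs_valid = obs[~np.isnan(obs)]

    grid = np.round(np.arange(grid_step, 1.0, grid_step), 10)
    # counts of |r| >= c via sorted search
    s = np.sort(obs_valid)
    observed_counts = len(s) - np.searchsorted(s, grid, side="left")

    perm_counts = np.zeros((n_perm, len(grid)))
    Y = matrix.to_numpy(dtype=float)
    for p in range(n_perm):
        Yp = rng.permuted(Y, axis=1)
        Rp = np.abs(_upper(pairwise_correlation(
            pd.DataFrame(Yp, index=matrix.index, columns=matrix.columns))))
        sp = np.sort(Rp[~np.isnan(Rp)])
        perm_counts[p] = len(sp) - np.searchsorted(sp, grid, side="left")
    permuted_counts = perm_counts.mean(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed_counts > 0, permuted_counts / observed_counts,
                       np.where(permuted_counts > 0, np.inf, 0.0))
    ok = np.flatnonzero(fdr <= alpha)
    if len(ok) == 0:
        raise ValueError("no significant correlation structure: no cutoff "
                         f"achieves FDR <= {alpha}")
    cutoff = float(grid[ok[0]])

    iu = np.triu_indices(len(genes), k=1)
    absr = np.abs(R[iu])
    keep = np.flatnonzero(~np.isnan(absr) & (absr >= cutoff))
    pairs = pd.DataFrame({
        "gene_a": genes[iu[0][keep]],
        "gene_b": genes[iu[1][keep]],
        "abs_r": absr[keep],
        "r": R[iu][keep],
    })
    pairs = pairs.sort_values(["abs_r", "gene_a", "gene_b"],
                              ascending=[False, True, True],
                              kind="mergesort").reset_index(drop=True)
    logger.info("permutation_fdr_threshold: cutoff |r|=%.2f keeps %d of %d "
                "pairs (FDR %.3g)", cutoff, len(pairs), len(obs_valid),
                float(fdr[ok[0]]))
    return CorrelationThresholdResult(grid, observed_counts, permuted_counts,
                                      fdr, cutoff, n_perm, pairs)


# ---------------------------------------------------------------- PMFG

def build_pfn(ranked_pairs: pd.DataFrame,
              nodes: list | None = None) -> nx.Graph:
    """Grow a planar filtered network by greedy edge insertion.

    ``ranked_pairs`` must be sorted by abs_r descending (ties by lexicographic
    gene pair). Each edge is added iff the graph stays planar; insertion stops
    at 3(n-2) edges. Edges carry ``weight`` (=|r|) and ``r`` attributes.

    Planarity bookkeeping: an edge joining two connected components can never
    break planarity, so it is accepted outright; an intra-component edge is
    tested on that component's subgraph alone, and saturated components
    (holding the planar maximum of 3(n_c - 2) edges) reject without testing.
    The result is identical to testing the whole graph at each step.
    """
    G = nx.Graph()
    if nodes is not None:
        G.add_nodes_from(nodes)
    all_nodes = set(G.nodes) | set(ranked_pairs["gene_a"]) | set(
        ranked_pairs["gene_b"])
    n = len(all_nodes)
    if n < 3:
        for row in ranked_pairs.itertuples(index=False):
            if row.gene_a != row.gene_b:
                G.add_edge(row.gene_a, row.gene_b,
                           weight=float(row.abs_r), r=float(row.r))
        return G
    max_edges = 3 * (n - 2)

    parent: dict = {}

    def find(x):
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:
            parent[x], x = root, parent[x]
        return root

    comp_nodes: dict = {}
    comp_edges: dict = {}
    ne = 0
    for row in ranked_pairs.itertuples(index=False):
        if ne >= max_edges:
            break
        a, b = row.gene_a, row.gene_b
        if a == b or G.has_edge(a, b):
            continue
        ra, rb = find(a), find(b)
        if ra != rb:
            na = comp_nodes.setdefault(ra, {a})
            nb = comp_nodes.setdefault(rb, {b})
            ea = comp_edges.setdefault(ra, [])
            eb = comp_edges.setdefault(rb, [])
            if len(na) < len(nb):
                ra, na, ea, nb, eb = rb, nb, eb, na, ea
            parent[find(a)] = ra
            parent[find(b)] = ra
            na |= nb
            ea += eb
            ea.append((a, b))
            comp_nodes[ra], comp_edges[ra] = na, ea
        else:
            cn, ce = comp_nodes[ra], comp_edges[ra]
            if len(ce) + 1 > 3 * (len(cn) - 2):
                continue  # component saturated: cannot stay planar
            H = nx.Graph(ce)
            H.add_edge(a, b)
            if not nx.check_planarity(H, counterexample=False)[0]:
                continue
            ce.append((a, b))
        G.add_edge(a, b, weight=float(row.abs_r), r=float(row.r))
        ne += 1
    assert nx.check_planarity(G, counterexample=False)[0]
    return G


# ------------------------------------------------------ multiscale modules

@dataclass
class Module:
    id: str
    genes: frozenset
    parent: str | None
    depth: int
    q: float | None  # modularity of the split that produced this module's level


@dataclass
class ModuleHierarchy:
    modules: list[Module]

    def by_id(self) -> dict[str, Module]:
        return {m.id: m for m in self.modules}

    def children(self, module_id: str) -> list[Module]:
        return [m for m in self.modules if m.parent == module_id]

    def leaves(self) -> list[Module]:
        parents = {m.parent for m in self.modules if m.parent is not None}
        return [m for m in self.modules if m.id not in parents]

    def eligible(self, min_size: int = 10, max_size: int = 500) -> list[Module]:
        """Modules inside the enrichment-eligible size window."""
        return [m for m in self.modules
                if min_size <= len(m.genes) <= max_size]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"module_id": m.id, "parent_id": m.parent or "root",
                 "depth": m.depth, "q": np.nan if m.q is None else m.q,
                 "size": len(m.genes), "genes": ",".join(sorted(m.genes))}
                for m in self.modules]
        return pd.DataFrame(rows)


def modularity_q(G: nx.Graph, partition: list[set]) -> float:
    """Weighted Newman modularity of a partition."""
    return nx.community.modularity(G, partition, weight="weight")


def _best_bipartition_exact(G: nx.Graph) -> tuple[list[set], float]:
    """Exhaustive search over all 2-way partitions; vectorized over bitmasks."""
    nodes = list(G.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    two_m = A.sum()
    if two_m == 0:
        return [set(nodes)], 0.0
    k = A.sum(axis=1)
    B = (A - np.outer(k, k) / two_m) / two_m
    masks = np.arange(1, 2 ** (n - 1))  # node n-1 fixed on side 0
    S = ((masks[:, None] >> np.arange(n)) & 1).astype(float)
    SB = S @ B
    q_vals = (SB * S).sum(axis=1) + ((1 - S) @ B * (1 - S)).sum(axis=1)
    best = int(np.argmax(q_vals))
    side = S[best].astype(bool)
    part = [{nodes[i] for i in range(n) if side[i]},
            {nodes[i] for i in range(n) if not side[i]}]
    return part, float(q_vals[best])


def best_modularity_partition(G: nx.Graph, seed: int,
                    exact_max_nodes: int = 14) -> tuple[list[set], float]:
    """Best modularity partition: exact 2-way search on small graphs,
    seeded Louvain on larger ones."""
    if G.number_of_nodes() <= exact_max_nodes:
        return _best_bipartition_exact(G)
    part = nx.community.louvain_communities(G, weight="weight", seed=seed)
    part = [set(c) for c in part]
    if len(part) < 2:
        return part, 0.0
    return part, modularity_q(G, part)


def _merge_small(G: nx.Graph, partition: list[set], min_size: int) -> list[set]:
    """Merge blocks below min_size into the sibling with the strongest total
    connecting edge weight (smallest blocks first)."""
    parts = [set(p) for p in partition]
    while True:
        small = [p for p in parts if len(p) < min_size]
        if not small or len(parts) < 2:
            break
        p = min(small, key=len)
        parts.remove(p)
        weights = []
        for q in parts:
            w = sum(d.get("weight", 1.0) for u in p
                    for _, v, d in G.edges(u, data=True) if v in q)
            weights.append(w)
        target = parts[int(np.argmax(weights))]
        target |= p
    return parts


def multiscale_cluster(network: nx.Graph, min_size: int = 10,
                       max_size: int = 500, seed: int = 0,
                       exact_max_nodes: int = 14) -> ModuleHierarchy:
    """Recursive top-down modularity partitioning of the planar network.

    The root module holds all network nodes. At each parent: disconnected
    parents first split into connected components; connected parents split by
    the best modularity partition, accepted iff Q > 0 and at least two blocks
    have >= min_size genes; undersized blocks are merged into their closest
    sibling; accepted children recurse. ``max_size`` only marks
    enrichment-eligibility, it does not limit splitting.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    counter = itertools.count(1)
    root = Module("M0", frozenset(network.nodes), None, 0, None)
    modules = [root]
    stack = [root]
    while stack:
        parent = stack.pop()
        sub = network.subgraph(parent.genes)
        if len(parent.genes) < 2 * min_size:
            continue
        comps = [set(c) for c in nx.connected_components(sub)]
        if len(comps) > 1:
            big = sorted((c for c in comps if len(c) >= min_size),
                         key=lambda c: (-len(c), min(map(str, c))))
            if not big:
                continue
            for c in big:
                child = Module(f"M{next(counter)}", frozenset(c), parent.id,
                               parent.depth + 1, None)
                modules.append(child)
                stack.append(child)
            continue
        part, q = best_modularity_partition(sub, seed=seed,
                                  exact_max_nodes=exact_max_nodes)
        n_big = sum(1 for p in part if len(p) >= min_size)
        if q <= 0 or n_big < 2:
            continue
        part = _merge_small(sub, part, min_size)
        part = sorted(part, key=lambda c: (-len(c), min(map(str, c))))
        for c in part:
            child = Module(f"M{next(counter)}", frozenset(c), parent.id,
                           parent.depth + 1, q)
            modules.append(child)
            stack.append(child)
    return ModuleHierarchy(modules)


# ---------------------------------------------------------------- hubs

@dataclass
class HubResult:
    node: str
    degree: int
    p: float
    is_hub: bool


def detect_hubs(network: nx.Graph, n_perm: int = 100, alpha: float = 0.05,
                seed: int | None = 0) -> list[HubResult]:
    """Flag nodes with higher connectivity than label-permuted planar nulls.

    The null planar network grown from the same ranked pair list with node
    labels permuted is isomorphic to the observed one (greedy insertion
    depends only on the weight order), so the null degree of a node is the
    observed degree of a uniformly chosen node: each permutation assigns node
    i the degree of position pi(i). p = (1 + #{null >= observed}) / (1 + n_perm),
    hub iff p < alpha.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if network.number_of_edges() < 1:
        raise ValueError("network has no edges")
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes, key=str)
    deg = np.array([network.degree(v) for v in nodes])
    n = len(nodes)
    exceed = np.zeros(n, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += deg[perm] >= deg
    p = (1 + exceed) / (1 + n_perm)
    return [HubResult(str(v), int(d), float(pv), bool(pv < alpha))
            for v, d, pv in zip(nodes, deg, p)]


def hubs_to_frame(hubs: list[HubResult]) -> pd.DataFrame:
    return pd.DataFrame([{"gene": h.node, "degree": h.degree, "p": h.p,
                          "is_hub": h.is_hub} for h in hubs])
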