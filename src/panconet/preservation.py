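"""Cross-cohort module preservation, clustering, and network aggregation.

Module similarity across cohorts combines the Jaccard index J = |A∩B|/|A∪B|
with a Fisher exact test on the shared gene universe (BH-corrected per cohort
pair). A module pair is conserved when J > 0.4 and aFETP < 0.05; a module is
specific when its best counterpart in every other cohort has J < 0.05 or
aFETP > 0.05. Conserved modules are grouped into module clusters by a greedy
frontier expansion over the conserved-pair relation, cohorts are clustered
hierarchically on their conservation profiles, and target modules from all
cohorts are merged into an aggregated network whose nodes and edges carry
cross-cohort conservation weights (nodes below weight 4 filtered).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .enrichment import bh_adjust, hypergeom_tail

logger = logging.getLogger("panconet")

ModuleKey = tuple[str, str]  # (cohort, module id)


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def _eligible_modules(hierarchy, size_bounds) -> dict[str, set[str]]:
    lo, hi = size_bounds
    return {m.id: set(m.genes) for m in hierarchy.modules
            if m.parent is not None and lo <= len(m.genes) <= hi}


def pairwise_similarity(hierarchies: dict[str, "ModuleHierarchy"],
                        size_bounds: tuple[int, int] = (10, 500),
                        jaccard_conserved: float = 0.4,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Jaccard + Fisher similarity for every cross-cohort module pair.

    The Fisher universe for a cohort pair is the intersection of the two
    cohorts' network gene universes (root module genes); BH correction is
    applied within each cohort-pair family. Returns one row per unordered
    pair with columns cohort_a, module_a, cohort_b, module_b, jaccard, p,
    adj_p, conserved.
    """
    if len(hierarchies) < 2:
        raise ValueError("need at least 2 cohorts")
    cohorts = sorted(hierarchies)
    universes = {c: set(next(m for m in hierarchies[c].modules
                             if m.parent is None).genes) for c in cohorts}
    eligible = {c: _eligible_modules(hierarchies[c], size_bounds)
                for c in cohorts}
    frames = []
    for i, ca in enumerate(cohorts):
        for cb in cohorts[i + 1:]:
            uni = universes[ca] & universes[cb]
            N = len(uni)
            if N == 0:
                continue
            rows = []
            for ma, ga in sorted(eligible[ca].items()):
                ga_u = ga & uni
                for mb, gb in sorted(eligible[cb].items()):
                    gb_u = gb & uni
                    k = len(ga_u & gb_u)
                    rows.append({
                        "cohort_a": ca, "module_a": ma,
                        "cohort_b": cb, "module_b": mb,
                        "jaccard": jaccard(ga, gb),
                        "p": hypergeom_tail(k, N, len(gb_u), len(ga_u)),
                    })
            if not rows:
                continue
            fam = pd.DataFrame(rows)
            fam["adj_p"] = bh_adjust(fam["p"].to_numpy())
            frames.append(fam)
    if not frames:
        raise ValueError("no eligible module pairs across cohorts")
    pairs = pd.concat(frames, ignore_index=True)
    pairs["conserved"] = ((pairs["jaccard"] > jaccard_conserved)
                          & (pairs["adj_p"] < alpha))
    return pairs


def classify_modules(pairs: pd.DataFrame,
                     jaccard_conserved: float = 0.4,
                     jaccard_specific: float = 0.05,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Label each module conserved / specific / intermediate.

    Conserved: at least one pair with J > 0.4 and aFETP < 0.05. Specific: in
    EVERY other cohort the best-matching counterpart (highest J) has J < 0.05
    or aFETP > 0.05 (cohorts with no computed counterpart count as no
    overlap). Otherwise intermediate.
    """
    sym = pd.concat([
        pairs.rename(columns={"cohort_a": "cohort", "module_a": "module",
                              "cohort_b": "other", "module_b":
                              "other_module"}),
        pairs.rename(columns={"cohort_b": "cohort", "module_b": "module",
                              "cohort_a": "other", "module_a":
                              "other_module"}),
    ], ignore_index=True)
    rows = []
    for (cohort, module), sub in sym.groupby(["cohort", "module"],
                                             sort=True):
        conserved = bool(sub["conserved"].any())
        specific = True
        for _, osub in sub.groupby("other"):
            best = osub.loc[osub["jaccard"].idxmax()]
            if not (best["jaccard"] < jaccard_specific
                    or best["adj_p"] > alpha):
                specific = False
                break
        if conserved:
            label = "conserved"
        elif specific:
            label = "specific"
        else:
            label = "intermediate"
        rows.append({"cohort": cohort, "module": module, "label": label,
                     "best_jaccard": float(sub["jaccard"].max())})
    return pd.DataFrame(rows)


@dataclass
class ModuleCluster:
    cluster_id: str
    members: list[ModuleKey]


def greedy_module_clusters(pairs: pd.DataFrame,
                           seed: int | None = None) -> list[ModuleCluster]:
    """Group conserved modules into clusters by greedy frontier expansion.

    Starting from an (arbitrary, optionally shuffled) unassigned conserved
    module, its conserved counterparts are pooled and re-searched until
    closure, the closed set becomes one cluster and leaves the search list.
    The resulting partition equals the connected components of the
    conserved-pair graph, so the output does not depend on the visit order;
    clusters are reported in a canonical sort with ids c1, c2, ...
    """
    conserved = pairs[pairs["conserved"]]
    adj: dict[ModuleKey, set[ModuleKey]] = {}
    for row in conserved.itertuples(index=False):
        a = (row.cohort_a, row.module_a)
        b = (row.cohort_b, row.module_b)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    todo = sorted(adj)
    if seed is not None:
        rng = np.random.default_rng(seed)
        todo = [todo[i] for i in rng.permutation(len(todo))]
    unassigned = set(adj)
    clusters: list[list[ModuleKey]] = []
    for start in todo:
        if start not in unassigned:
            continue
        cluster = {start}
        frontier = {start}
        while frontier:  # pool counterparts until no new module appears
            nxt = set()
            for m in frontier:
                nxt |= adj[m] & unassigned - cluster
            cluster |= nxt
            frontier = nxt
        unassigned -= cluster
        clusters.append(sorted(cluster))
    clusters.sort(key=lambda ms: (-len(ms), ms))
    return [ModuleCluster(f"c{i + 1}", ms)
            for i, ms in enumerate(clusters)]


def cluster_cohorts(pairs: pd.DataFrame,
                    clusters: list[ModuleCluster] | None = None,
                    cut: float = 0.7,
                    method: str = "average") -> dict:
    """Hierarchically cluster cohorts on their conserved-module profiles.

    Each cohort's profile over module clusters holds the maximum Jaccard of
    its conserved pairs inside that cluster (0 when absent); cohort distance
    is 1 - cosine similarity of profiles, linkage is average by default.
    Returns {"linkage": Z, "cohorts": order, "groups": labels,
    "distance": condensed}.
    """
    cohorts = sorted(set(pairs["cohort_a"]) | set(pairs["cohort_b"]))
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    if clusters is None:
        clusters = greedy_module_clusters(pairs)
    member_of = {m: cl.cluster_id for cl in clusters for m in cl.members}
    profile = pd.DataFrame(0.0, index=cohorts,
                           columns=[cl.cluster_id for cl in clusters])
    conserved = pairs[pairs["conserved"]]
    for row in conserved.itertuples(index=False):
        a = (row.cohort_a, row.module_a)
        cid = member_of.get(a)
        if cid is None:
            continue
        for cohort in (row.cohort_a, row.cohort_b):
            profile.loc[cohort, cid] = max(profile.loc[cohort, cid],
                                           row.jaccard)
    P = profile.to_numpy()
    norms = np.linalg.norm(P, axis=1)
    sim = np.zeros((len(cohorts), len(cohorts)))
    for i in range(len(cohorts)):
        for j in range(len(cohorts)):
            if norms[i] == 0 or norms[j] == 0:
                sim[i, j] = 1.0 if i == j else 0.0
            else:
                sim[i, j] = P[i] @ P[j] / (norms[i] * norms[j])
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=method)
    labels = fcluster(Z, t=cut, criterion="distance")
    return {"linkage": Z, "cohorts": cohorts,
            "groups": dict(zip(cohorts, (int(x) for x in labels))),
            "distance": condensed, "profile": profile}


def aggregate_network(target_modules: dict[str, list[set[str]]],
                      networks: dict[str, nx.Graph],
                      min_weight: int = 4) -> nx.Graph:
    """Merge target-module subnetworks across cohorts with conservation weights.

    Node weight = number of cohorts whose target modules contain the gene;
    edge weight = number of cohorts whose planar network links the pair
    within that cohort's target genes. Nodes with weight < min_weight are
    removed together with their incident edges.
    """
    if not target_modules or all(not v for v in target_modules.values()):
        raise ValueError("empty target module sets")
    node_w: dict[str, int] = {}
    edge_w: dict[tuple[str, str], int] = {}
    for cohort, modules in target_modules.items():
        genes = set().union(*modules) if modules else set()
        for gene in genes:
            node_w[gene] = node_w.get(gene, 0) + 1
        net = networks.get(cohort)
        if net is None:
            continue
        for u, v in net.subgraph(genes).edges:
            key = (u, v) if str(u) <= str(v) else (v, u)
            edge_w[key] = edge_w.get(key, 0) + 1
    G = nx.Graph()
    for gene, w in node_w.items():
        if w >= min_weight:
            G.add_node(gene, weight=w)
    for (u, v), w in edge_w.items():
        if u in G and v in G:
            G.add_edge(u, v, weight=w)
    logger.info("aggregate_network: %d/%d nodes pass weight >= %d; %d edges",
                G.number_of_nodes(), len(node_w), min_weight,
                G.number_of_edges())
    return G


def pairs_to_tsv(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def clusters_to_json(clusters: list[ModuleCluster]) -> dict:
    return {cl.cluster_id: [list(m) for m in cl.members] for cl in clusters}
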