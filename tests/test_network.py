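import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from panconet.network import (best_modularity_partition, build_pfn,
                              detect_hubs, modularity_q, multiscale_cluster,
                              permutation_fdr_threshold)


def ranked_frame(edges):
    """edges: iterable of (a, b, weight) -> sorted ranked-pair frame."""
    df = pd.DataFrame(edges, columns=["gene_a", "gene_b", "abs_r"])
    df["r"] = df["abs_r"]
    return df.sort_values(["abs_r", "gene_a", "gene_b"],
                          ascending=[False, True, True]).reset_index(drop=True)


def naive_pfn(pairs: pd.DataFrame) -> nx.Graph:
    """Brute-force greedy insertion testing whole-graph planarity each step."""
    nodes = sorted(set(pairs["gene_a"]) | set(pairs["gene_b"]), key=str)
    G = nx.Graph()
    max_edges = 3 * (len(nodes) - 2) if len(nodes) >= 3 else np.inf
    for row in pairs.itertuples(index=False):
        if G.number_of_edges() >= max_edges:
            break
        if row.gene_a == row.gene_b or G.has_edge(row.gene_a, row.gene_b):
            continue
        G.add_edge(row.gene_a, row.gene_b, weight=row.abs_r)
        if not nx.check_planarity(G, counterexample=False)[0]:
            G.remove_edge(row.gene_a, row.gene_b)
    return G


class TestPermutationFdr:
    def test_identical_rows_survive_any_cutoff(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(20, 30)),
                         index=[f"g{i}" for i in range(20)])
        m.loc["g1"] = m.loc["g0"]  # perfect pair
        res = permutation_fdr_threshold(m, n_perm=5, seed=0)
        top = res.pairs.iloc[0]
        assert {top.gene_a, top.gene_b} == {"g0", "g1"}
        assert top.abs_r == pytest.approx(1.0)

    def test_null_matrix_yields_error_or_almost_nothing(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(500, 100)),
                         index=[f"g{i}" for i in range(500)])
        try:
            res = permutation_fdr_threshold(m, n_perm=10, seed=1)
            frac = len(res.pairs) / (500 * 499 / 2)
            assert frac < 0.001
        except ValueError as e:
            assert "no significant correlation" in str(e)

    def test_planted_two_block_structure_recovered(self):
        rng = np.random.default_rng(2)
        n_s = 100
        blocks = []
        for _ in range(2):
            f = rng.normal(size=n_s)
            blocks.append(np.sqrt(.9) * f
                          + np.sqrt(.1) * rng.normal(size=(25, n_s)))
        m = pd.DataFrame(np.vstack(blocks + [rng.normal(size=(50, n_s))]),
                         index=[f"g{i:03d}" for i in range(100)])
        res = permutation_fdr_threshold(m, n_perm=10, seed=2)
        assert res.chosen_cutoff <= 0.9
        within = {frozenset((f"g{i:03d}", f"g{j:03d}"))
                  for b in (0, 1)
                  for i, j in itertools.combinations(
                      range(25 * b, 25 * b + 25), 2)}
        found = {frozenset((a, b))
                 for a, b in zip(res.pairs.gene_a, res.pairs.gene_b)}
        assert len(within & found) / len(within) >= 0.95

    def test_fdr_chosen_is_smallest_cutoff_meeting_alpha(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=50)
        m = pd.DataFrame(np.vstack([np.sqrt(.8) * f + np.sqrt(.2)
                                    * rng.normal(size=(10, 50)),
                                    rng.normal(size=(40, 50))]),
                         index=[f"g{i}" for i in range(50)])
        res = permutation_fdr_threshold(m, n_perm=10, alpha=0.05, seed=3)
        i = np.flatnonzero(res.cutoffs == res.chosen_cutoff)[0]
        assert res.fdr[i] <= 0.05
        assert (res.fdr[:i] > 0.05).all()


class TestBuildPfn:
    def test_k5_drops_exactly_the_lightest_edge(self):
        nodes = list("abcde")
        weights = iter(np.linspace(1.0, 0.1, 10))
        edges = [(u, v, next(weights))
                 for u, v in itertools.combinations(nodes, 2)]
        pairs = ranked_frame(edges)
        G = build_pfn(pairs)
        assert G.number_of_edges() == 9  # 3(5-2)
        missing = [tuple(e[:2]) for e in edges if not G.has_edge(*e[:2])]
        lightest = min(edges, key=lambda e: e[2])
        assert missing == [lightest[:2]]
        assert nx.check_planarity(G, counterexample=False)[0]

    def test_k6_matches_bruteforce_greedy(self):
        rng = np.random.default_rng(4)
        edges = [(u, v, w) for (u, v), w in zip(
            itertools.combinations("abcdef", 2), rng.permutation(15) + 1.0)]
        pairs = ranked_frame(edges)
        G = build_pfn(pairs)
        oracle = naive_pfn(pairs)
        assert G.number_of_edges() == 12  # 3(6-2)
        assert set(map(frozenset, G.edges)) == set(map(frozenset,
                                                       oracle.edges))

    def test_tree_input_returned_unchanged(self):
        edges = [("a", "b", .9), ("b", "c", .8), ("b", "d", .7),
                 ("d", "e", .6)]
        G = build_pfn(ranked_frame(edges))
        assert set(map(frozenset, G.edges)) == {frozenset(e[:2])
                                                for e in edges}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        iu = list(itertools.combinations(range(n), 2))
        idx = rng.choice(len(iu), size=40, replace=False)
        edges = [(f"n{iu[i][0]:02d}", f"n{iu[i][1]:02d}", float(w))
                 for i, w in zip(idx, rng.permutation(40) + 1.0)]
        pairs = ranked_frame(edges)
        G = build_pfn(pairs)
        oracle = naive_pfn(pairs)
        assert set(map(frozenset, G.edges)) == set(map(frozenset,
                                                       oracle.edges))
        assert nx.check_planarity(G, counterexample=False)[0]

    def test_edge_weight_attributes_kept(self):
        G = build_pfn(ranked_frame([("a", "b", .5)]))
        assert G["a"]["b"]["weight"] == .5


def exhaustive_best_bipartition_q(G):
    """Independent oracle: maximize Q over all 2-way partitions, evaluating
    the double sum sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j) / 2m
    mask by mask."""
    nodes = list(G.nodes)
    n = len(nodes)
    A = np.zeros((n, n))
    pos = {u: i for i, u in enumerate(nodes)}
    for u, v, d in G.edges(data=True):
        w = d.get("weight", 1.0)
        A[pos[u], pos[v]] = w
        A[pos[v], pos[u]] = w
    two_m = A.sum()
    k = A.sum(axis=1)
    B = A - np.outer(k, k) / two_m
    best = -np.inf
    bits = np.arange(n)
    for mask in range(1, 2 ** (n - 1)):
        s = ((mask >> bits) & 1).astype(float)
        q = (s @ B @ s + (1 - s) @ B @ (1 - s)) / two_m
        best = max(best, q)
    return best


class TestMultiscaleCluster:
    def test_two_cliques_with_bridge_split_at_cliques(self):
        G = nx.Graph()
        for base in (0, 10):
            for u, v in itertools.combinations(range(base, base + 10), 2):
                G.add_edge(u, v, weight=1.0)
        G.add_edge(0, 10, weight=1.0)
        h = multiscale_cluster(G, min_size=10, exact_max_nodes=20)
        children = h.children("M0")
        assert sorted(len(c.genes) for c in children) == [10, 10]
        assert {frozenset(c.genes) for c in children} == {
            frozenset(range(10)), frozenset(range(10, 20))}
        assert children[0].q == pytest.approx(
            exhaustive_best_bipartition_q(G), abs=1e-9)

    def test_nine_gene_module_never_split(self):
        G = nx.complete_graph(9)
        for u, v in G.edges:
            G[u][v]["weight"] = 1.0
        h = multiscale_cluster(G, min_size=10)
        assert len(h.modules) == 1  # root only
        assert h.eligible(10, 500) == []

    def test_planted_four_blocks_recovered(self):
        rng = np.random.default_rng(5)
        n_s = 150
        rows, truth = [], {}
        for b in range(4):
            f = rng.normal(size=n_s)
            for i in range(15):
                g = f"b{b}g{i:02d}"
                rows.append((g, np.sqrt(.75) * f
                             + np.sqrt(.25) * rng.normal(size=n_s)))
                truth[g] = b
        m = pd.DataFrame(dict(rows)).T
        res = permutation_fdr_threshold(m, n_perm=5, seed=5)
        net = build_pfn(res.pairs)
        h = multiscale_cluster(net, min_size=10, seed=5)
        detected = {}
        for leaf in h.leaves():
            for g in leaf.genes:
                detected[g] = leaf.id
        from sklearn.metrics import adjusted_rand_score
        genes = sorted(truth)
        ari = adjusted_rand_score([truth[g] for g in genes],
                                  [detected.get(g, "?") for g in genes])
        assert ari >= 0.9

    def test_hierarchy_nests_and_siblings_disjoint(self, hierarchies):
        for h in hierarchies.values():
            by_id = h.by_id()
            for m in h.modules:
                if m.parent is not None:
                    assert m.genes < by_id[m.parent].genes or \
                        m.genes == by_id[m.parent].genes
                kids = h.children(m.id)
                for a, b in itertools.combinations(kids, 2):
                    assert not (a.genes & b.genes)
                for kid in kids:
                    assert len(kid.genes) >= 10

    def test_disconnected_parent_splits_into_components(self):
        G = nx.Graph()
        for base in (0, 100):
            for u, v in itertools.combinations(range(base, base + 12), 2):
                G.add_edge(u, v, weight=1.0)
        h = multiscale_cluster(G, min_size=10)
        comps = h.children("M0")
        assert sorted(len(c.genes) for c in comps) == [12, 12]


class TestBestPartition:
    @pytest.mark.parametrize("seed", range(5))
    def test_exact_bipartition_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        G = nx.gnp_random_graph(n, 0.5, seed=seed + 100)
        while not nx.is_connected(G) or G.number_of_edges() == 0:
            seed += 1000
            G = nx.gnp_random_graph(n, 0.5, seed=seed)
        for u, v in G.edges:
            G[u][v]["weight"] = float(rng.integers(1, 10))
        part, q = best_modularity_partition(G, seed=0)
        assert q == pytest.approx(exhaustive_best_bipartition_q(G), abs=1e-9)
        assert q == pytest.approx(modularity_q(G, part), abs=1e-12)


class TestDetectHubs:
    def test_regular_graph_flags_nothing(self):
        G = nx.cycle_graph(20)
        res = detect_hubs(G, n_perm=100, seed=0)
        assert not any(h.is_hub for h in res)
        assert all(h.p == 1.0 for h in res)

    def test_star_center_is_hub_leaves_are_not(self):
        G = nx.star_graph(50)
        res = {h.node: h for h in detect_hubs(G, n_perm=200, seed=0)}
        assert res["0"].is_hub
        assert not any(res[str(i)].is_hub for i in range(1, 51))

    def test_p_values_in_unit_interval(self):
        G = nx.gnp_random_graph(30, 0.2, seed=7)
        for h in detect_hubs(G, n_perm=50, seed=1):
            assert 0 < h.p <= 1

    def test_requires_permutations_and_edges(self):
        with pytest.raises(ValueError):
            detect_hubs(nx.star_graph(3), n_perm=0)
        with pytest.raises(ValueError):
            detect_hubs(nx.empty_graph(5), n_perm=10)


def test_planarity_invariant_on_pipeline_networks(run_dir):
    import pandas as pd
    for label in ("C1", "C2", "C3"):
        edges = pd.read_csv(run_dir / f"{label}.edges.tsv", sep="\t")
        G = nx.from_pandas_edgelist(edges, "gene_a", "gene_b")
        assert nx.check_planarity(G, counterexample=False)[0]
        assert G.number_of_edges() <= 3 * (G.number_of_nodes() - 2)
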