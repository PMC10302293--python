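"""Median-joining haplotype networks (Bandelt, Forster & Röhl 1999).

The algorithm alternates two steps until the node set is stable: build the
epsilon-relaxed minimum spanning network (MSN) over the current haplotypes
(observed plus previously inferred median vectors), then for triplets of
mutually linked nodes add quasi-median vectors — the consensus sequences
taking the majority state per character, with three-way ties spawning every
resolution — whenever they cheapen the local connection.  Median vectors that
end up with degree <= 2 are pruned (by the triangle inequality of Hamming
distance a degree-2 intermediate never shortens a path).  Tie-breaking is
lexicographic throughout, so the construction is deterministic.

Edges carry the number of character differences; node payloads carry observed
frequencies per deme and group so exports preserve the usual
node-size-proportional-to-frequency semantics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from cherrypop.errors import ConvergenceError, InputError
from cherrypop.seqdata import HaplotypeTable


@dataclass
class HaploNetwork:
    graph: nx.Graph  # nodes: haplotype ids / "mv<i>"; edges: weight=int
    epsilon: int
    observed_ids: list[str]
    median_ids: list[str]
    sequences: dict[str, str]

    @property
    def total_length(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tweight\n")
            for a, b, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{a}\t{b}\t{int(d['weight'])}\n")

    def write_node_table(self, path) -> None:
        import pandas as pd

        rows = []
        for node, data in sorted(self.graph.nodes(data=True)):
            row = {"node": node, "observed": data.get("observed", False),
                   "frequency": data.get("frequency", 0)}
            row.update(
                {k: v for k, v in data.items() if k.startswith("freq_")}
            )
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _hamming(a: tuple, b: tuple) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _distance_matrix(seqs: list[tuple]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs])
    n = arr.shape[0]
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i, i + 1 :] = (arr[i] != arr[i + 1 :]).sum(axis=1)
    return d + d.T


def _minimax_thresholds(d: np.ndarray) -> np.ndarray:
    """t[i, j] = max edge weight on the MST path between i and j."""
    n = d.shape[0]
    mst = minimum_spanning_tree(d.astype(float)).toarray()
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if mst[i, j] > 0:
                adj[i].append((j, mst[i, j]))
                adj[j].append((i, mst[i, j]))
    t = np.zeros((n, n))
    for src in range(n):
        # DFS over the tree carrying the running max edge weight
        stack = [(src, -1, 0.0)]
        while stack:
            node, parent, running = stack.pop()
            t[src, node] = running
            for nb, w in adj[node]:
                if nb != parent:
                    stack.append((nb, node, max(running, w)))
    return t


def _feasible_links(d: np.ndarray, epsilon: int) -> set[tuple[int, int]]:
    """Links of the epsilon-relaxed minimum spanning network.

    A pair is linked when its direct distance does not exceed the minimax
    (MST bottleneck) distance plus epsilon; with epsilon 0 this is the classic
    minimum spanning network (union of all MSTs).
    """
    t = _minimax_thresholds(d)
    n = d.shape[0]
    return {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if d[i, j] <= t[i, j] + epsilon
    }


def _quasi_medians(u: tuple, v: tuple, w: tuple, cap: int = 64) -> list[tuple]:
    """Quasi-median sequences of three rows: majority per site, ties branch."""
    site_options: list[tuple] = []
    n_comb = 1
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            site_options.append((a,))
        elif b == c:
            site_options.append((b,))
        else:
            site_options.append(tuple(sorted({a, b, c})))
            n_comb *= len(site_options[-1])
            if n_comb > cap:
                return []  # combinatorial blow-up: skip this triplet
    return [tuple(s) for s in itertools.product(*site_options)]


def median_joining(
    ht: HaplotypeTable, epsilon: int = 0, max_iter: int = 100
) -> HaploNetwork:
    """Median-joining network over the haplotypes of ``ht``.

    Characters are treated as unordered multistate (nucleotides plus binary
    indel characters alike).  ``epsilon`` relaxes both the spanning-network
    links and the median acceptance cost, reproducing the tolerance parameter
    of the original algorithm; 0 gives the sparsest network.
    """
    if ht.n_haplotypes < 2:
        raise InputError("median-joining needs at least 2 haplotypes")
    observed = [tuple(r) for r in ht.rows]
    if len(set(observed)) != len(observed):
        raise InputError("haplotype rows must be distinct")
    observed_set = set(observed)

    def pruned_network(nodes: list[tuple]):
        """Iteratively drop unsampled nodes of degree <= 2 (a degree-2
        intermediate never shortens a Hamming path); return nodes, links, d."""
        nodes = sorted(set(nodes))
        while True:
            d = _distance_matrix(nodes)
            links = _feasible_links(d, epsilon)
            degree = {i: 0 for i in range(len(nodes))}
            for i, j in links:
                degree[i] += 1
                degree[j] += 1
            keep = [
                x for i, x in enumerate(nodes)
                if x in observed_set or degree[i] >= 3
            ]
            if len(keep) == len(nodes):
                return nodes, links, d
            nodes = keep

    X, links, d = pruned_network(list(observed))
    length = sum(d[i, j] for i, j in links)

    for _ in range(max_iter):
        # candidate quasi-medians from triplets with >= 2 feasible links
        neigh: dict[int, set[int]] = {i: set() for i in range(len(X))}
        for i, j in links:
            neigh[i].add(j)
            neigh[j].add(i)
        candidates: dict[tuple, int] = {}
        for u in range(len(X)):
            for v, w in itertools.combinations(sorted(neigh[u]), 2):
                for m in _quasi_medians(X[u], X[v], X[w]):
                    if m in candidates or m in X:
                        continue
                    cost = _hamming(X[u], m) + _hamming(X[v], m) + _hamming(X[w], m)
                    candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        additions = sorted(m for m, c in candidates.items() if c <= lam + epsilon)
        # admit the batch only if it shortens the (pruned) network
        X_try, links_try, d_try = pruned_network(X + additions)
        length_try = sum(d_try[i, j] for i, j in links_try)
        if length_try < length - 1e-9:
            X, links, d, length = X_try, links_try, d_try, length_try
        else:
            break
    else:
        raise ConvergenceError(
            f"median-joining did not stabilize after {max_iter} iterations "
            f"({len(X)} nodes)"
        )
    seq_to_id: dict[tuple, str] = {}
    for hid, row in zip(ht.ids, ht.rows):
        seq_to_id[tuple(row)] = hid
    mv_counter = itertools.count(1)
    for x in X:
        if x not in seq_to_id:
            seq_to_id[x] = f"mv{next(mv_counter)}"

    g = nx.Graph()
    groups = sorted({ht.deme_meta[d_][1] for d_ in ht.demes})
    group_counts = {grp: np.zeros(ht.n_haplotypes) for grp in groups}
    for j, deme in enumerate(ht.demes):
        group_counts[ht.deme_meta[deme][1]] += ht.counts[:, j]
    id_index = {hid: i for i, hid in enumerate(ht.ids)}
    for x in X:
        node = seq_to_id[x]
        obs = x in observed_set
        attrs = {"observed": obs, "sequence": "".join(x)}
        if obs:
            i = id_index[node]
            attrs["frequency"] = int(ht.counts[i].sum())
            for grp in groups:
                attrs[f"freq_{grp}"] = int(group_counts[grp][i])
        else:
            attrs["frequency"] = 0
        g.add_node(node, **attrs)
    for i, j in sorted(links):
        g.add_edge(seq_to_id[X[i]], seq_to_id[X[j]], weight=int(d[i, j]))

    return HaploNetwork(
        graph=g,
        epsilon=epsilon,
        observed_ids=list(ht.ids),
        median_ids=sorted(
            (seq_to_id[x] for x in X if x not in observed_set),
            key=lambda s: int(s[2:]),
        ),
        sequences={seq_to_id[x]: "".join(x) for x in X},
    )


def network_summaries(net: HaploNetwork):
    """Per-node degree, betweenness rank, frequency and group composition."""
    import pandas as pd

    g = net.graph
    betw = nx.betweenness_centrality(g, weight=None)
    order = sorted(betw, key=lambda n: (-betw[n], n))
    rank = {n: r + 1 for r, n in enumerate(order)}
    rows = []
    for node in sorted(g.nodes):
        data = g.nodes[node]
        freq = data.get("frequency", 0)
        comp = {
            k.replace("freq_", "pct_"): (100.0 * v / freq if freq else 0.0)
            for k, v in data.items()
            if k.startswith("freq_")
        }
        rows.append(
            {
                "node": node,
                "observed": data.get("observed", False),
                "degree": g.degree[node],
                "betweenness": betw[node],
                "betweenness_rank": rank[node],
                "frequency": freq,
                **{k: round(v, 2) for k, v in sorted(comp.items())},
            }
        )
    return pd.DataFrame(rows)


def cut_sublineages(net: HaploNetwork, max_weight: int) -> list[set[str]]:
    """Connected components after removing edges heavier than ``max_weight``.

    A rough network-intrinsic lineage delimitation utility (this is a simple
    edge cut, not a model-based clustering).
    """
    g = net.graph.copy()
    g.remove_edges_from(
        [(a, b) for a, b, d in g.edges(data=True) if d["weight"] > max_weight]
    )
    return [set(c) for c in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])]


def mst_length(ht: HaplotypeTable) -> float:
    """Total length of a minimum spanning tree over the observed haplotypes."""
    d = _distance_matrix([tuple(r) for r in ht.rows])
    return float(minimum_spanning_tree(d.astype(float)).sum())


def msn_length(ht: HaplotypeTable, epsilon: int = 0) -> float:
    """Total length of the epsilon-relaxed minimum spanning network over the
    observed haplotypes (no median vectors)."""
    d = _distance_matrix([tuple(r) for r in ht.rows])
    return float(sum(d[i, j] for i, j in _feasible_links(d, epsilon)))
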