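"""Median-joining haplotype networks with geographic annotation.

The network starts from the minimum spanning network (MSN) over sampled
haplotypes (all links within ``epsilon`` of the smallest distance connecting
two components are feasible) and iteratively adds median vectors — per-site
consensus sequences of node triplets — whenever they reduce the minimum
spanning tree length of the node set.  Median vectors that end up connecting
fewer than two neighbours are discarded.  Ambiguous bases count as missing
for Hamming distances; tie-breaking is lexicographic so output is
deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .seqio import HaplotypeTable, PopulationMap

__all__ = ["HaplotypeNetwork", "median_joining", "annotate_frequencies",
           "assign_haplotype_groups", "hamming"]


def hamming(a: str, b: str) -> int:
    """Hamming distance over sites unambiguous in both sequences."""
    return sum(
        1 for x, y in zip(a, b)
        if x != y and x in "ACGT" and y in "ACGT"
    )


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph                      # nodes carry 'seq' and 'sampled'
    sequences: dict[str, str]
    sampled: set[str]
    epsilon: int
    region_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def medians(self) -> set[str]:
        return set(self.sequences) - self.sampled

    def total_length(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def mst_length(self) -> int:
        seqs = list(self.sequences.values())
        return _mst_length(seqs)


from .seqio import _CODE_LUT, MISSING


def _dist_matrix(seqs: list[str]) -> np.ndarray:
    m = len(seqs)
    L = len(seqs[0])
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw.reshape(m, L)]
    ok = codes != MISSING
    D = np.zeros((m, m), dtype=int)
    for i in range(m):
        valid = ok[i] & ok[i + 1:]
        D[i, i + 1:] = ((codes[i] != codes[i + 1:]) & valid).sum(axis=1)
    return D + D.T


def _mst_length(seqs: list[str]) -> int:
    if len(seqs) < 2:
        return 0
    D = _dist_matrix(seqs).astype(float)
    return int(round(minimum_spanning_tree(D).sum()))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def minimum_spanning_network(D: np.ndarray, epsilon: int = 0) -> list[tuple[int, int]]:
    """Feasible links: pairs whose distance is within ``epsilon`` of the
    threshold at which their components first connect (Bandelt's MSN)."""
    m = D.shape[0]
    # connection threshold per pair via Kruskal sweep over distinct distances
    thresh = np.zeros((m, m))
    uf = _UnionFind(m)
    pairs = [(D[i, j], i, j) for i in range(m) for j in range(i + 1, m)]
    pending = [(i, j) for i in range(m) for j in range(i + 1, m)]
    for d in sorted({p[0] for p in pairs}):
        # record threshold for pairs that become connected at this level
        newly = []
        for (dd, i, j) in pairs:
            if dd == d:
                newly.append((i, j))
        for i, j in newly:
            uf.union(i, j)
        still = []
        for i, j in pending:
            if uf.find(i) == uf.find(j):
                thresh[i, j] = thresh[j, i] = d
            else:
                still.append((i, j))
        pending = still
    edges = [
        (i, j) for i in range(m) for j in range(i + 1, m)
        if D[i, j] <= thresh[i, j] + epsilon
    ]
    return edges


def _median_seq(a: str, b: str, c: str) -> str:
    """Per-site majority of three sequences; unresolved three-way ties take
    the lexicographically smallest unambiguous state; all-missing sites stay N."""
    out = []
    for x, y, z in zip(a, b, c):
        states = [s for s in (x, y, z) if s in "ACGT"]
        if not states:
            out.append("N")
            continue
        best, bestc = None, 0
        for s in sorted(set(states)):
            cnt = states.count(s)
            if cnt > bestc:
                best, bestc = s, cnt
        out.append(best)
    return "".join(out)


def median_joining(ht: HaplotypeTable, epsilon: int = 0) -> HaplotypeNetwork:
    """Bandelt-style median-joining network over a haplotype table."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if ht.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")

    names = list(ht.sequences)
    seqs = {h: ht.sequences[h] for h in names}
    sampled = set(names)
    median_k = 0

    while True:
        order = sorted(seqs)
        slist = [seqs[h] for h in order]
        D = _dist_matrix(slist)
        edges = minimum_spanning_network(D, epsilon)
        G = nx.Graph()
        for h in order:
            G.add_node(h, seq=seqs[h], sampled=h in sampled)
        for i, j in edges:
            G.add_edge(order[i], order[j], weight=int(D[i, j]))

        # prune obsolete median vectors (degree <= 1, unsampled)
        removed = False
        for h in list(G.nodes):
            if h not in sampled and G.degree(h) <= 1:
                G.remove_node(h)
                del seqs[h]
                removed = True
        if removed:
            continue

        # propose medians for triplets centred on an MSN node
        cur_mst = _mst_length(list(seqs.values()))
        existing = set(seqs.values())
        best: tuple[int, str] | None = None   # (gain, seq), max gain then lex
        seen: set[str] = set()
        for u in G.nodes:
            nbrs = sorted(G.neighbors(u))
            for v, w in itertools.combinations(nbrs, 2):
                m = _median_seq(seqs[u], seqs[v], seqs[w])
                if m in existing or m in seen:
                    continue
                seen.add(m)
                gain = cur_mst - _mst_length(list(seqs.values()) + [m])
                if gain > 0 and (
                    best is None or gain > best[0]
                    or (gain == best[0] and m < best[1])
                ):
                    best = (gain, m)
        if best is None:
            break
        median_k += 1
        seqs[f"mv{median_k}"] = best[1]

    net = HaplotypeNetwork(G, dict(seqs), sampled & set(G.nodes), epsilon)
    return net


def annotate_frequencies(
    net: HaplotypeNetwork, ht: HaplotypeTable, pm: PopulationMap,
    scheme: dict[str, str] | None = None,
) -> HaplotypeNetwork:
    """Attach per-region sample counts to each node (zeros for medians).

    ``scheme`` maps population -> region; defaults to the popmap's regions.
    """
    pop_region = scheme if scheme is not None else pm.pop_to_region
    regions = sorted(set(pop_region.values()))
    counts: dict[str, dict[str, int]] = {}
    for h in net.graph.nodes:
        tab = {r: 0 for r in regions}
        if h in net.sampled:
            for pop, c in ht.counts.get(h, {}).items():
                if pop not in pop_region:
                    raise KeyError(f"scheme missing population {pop!r}")
                tab[pop_region[pop]] += c
        counts[h] = tab
        net.graph.nodes[h]["region_counts"] = tab
    net.region_counts = counts
    return net


def assign_haplotype_groups(
    net: HaplotypeNetwork, group_definitions: dict[str, list[str]]
) -> dict[str, str]:
    """Label sampled haplotypes by named group; others become 'unassigned'."""
    label: dict[str, str] = {}
    for grp, haps in group_definitions.items():
        for h in haps:
            if h in label:
                raise ValueError(f"haplotype {h!r} assigned to two groups")
            label[h] = grp
    return {
        h: label.get(h, "unassigned") for h in net.sampled
    }
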