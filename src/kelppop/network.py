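"""Statistical-parsimony (TCS-style) haplotype network construction.

Haplotype pairs are linked, most-similar first, as long as the number of
observed differences j stays within the 95% *parsimony connection limit*:
the largest j for which the probability that the j differences arose without
superimposed (homoplasious) change is at least 0.95. Multi-step links are
realised as chains through inferred intermediate nodes ("median vectors"),
so every edge in the network represents exactly one substitution.

The probability-of-parsimony calculation follows the statistical-parsimony
logic on a finite-sites model: mutations strike the m analysed columns
uniformly, a column comparing two states shows a difference iff it was hit
an odd number of times, and the true number of mutations H separating a
sequence pair is geometrically distributed (the pairwise coalescent result
for a neutral locus), with its mean fixed so that the expected number of
visible differences equals the observed j. The parsimony probability is then
the posterior probability that H equals j — i.e. that no column was struck
more than once.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .haplotypes import HaplotypeTable

__all__ = [
    "ParsimonyLimit",
    "HaplotypeNetwork",
    "parsimony_probability",
    "connection_limit",
    "build_network",
    "export_network",
]


def _difference_distributions(m: int, h_max: int) -> list[np.ndarray]:
    """P(D = d | H = h) for h = 0..h_max under uniform hits on m two-state sites.

    D performs a birth-death walk on {0..m}: each mutation flips a uniformly
    chosen column, so D -> D+1 with probability (m-D)/m and D -> D-1 with
    probability D/m.
    """
    dists = [np.array([1.0])]
    cur = dists[0]
    for h in range(1, h_max + 1):
        nxt = np.zeros(min(h, m) + 1)
        for d, p in enumerate(cur):
            if p == 0.0:
                continue
            if d > 0:
                nxt[d - 1] += p * d / m
            if d < m:
                nxt[d + 1] += p * (m - d) / m
        dists.append(nxt)
        cur = nxt
    return dists


def parsimony_probability(j: int, L_used: int) -> float:
    """Probability that j observed differences over L_used sites are parsimonious.

    Returns P(H = j | D = j): the posterior probability that the true number
    of mutations separating the pair equals the observed difference count,
    i.e. that no superimposed changes occurred. Decreasing in j at fixed
    L_used; equals 1 at j = 0.
    """
    if j < 0:
        raise ValueError("j must be >= 0")
    if L_used < 1:
        raise ValueError("L_used must be >= 1")
    if j == 0:
        return 1.0
    m = L_used
    if 2 * j >= m:
        # expected visible differences saturate below m/2: no finite prior
        # mean reproduces j, and homoplasy is effectively certain
        return 0.0
    # Geometric prior on H with mean theta chosen so E[D] = j.
    # E[D | theta] = theta * m / (m + 2 theta)  =>  theta = j m / (m - 2 j).
    theta = j * m / (m - 2 * j)
    r = theta / (1.0 + theta)

    h_cap = j + 2 * max(50, 20 * j)
    dists = _difference_distributions(m, h_cap)
    numerator = r**j * dists[j][j]
    denom = 0.0
    for h in range(j, h_cap + 1, 2):  # parity: D = j needs H = j, j+2, ...
        term = r**h * dists[h][j] if j < len(dists[h]) else 0.0
        denom += term
        if h > j + 10 and term < 1e-15 * denom:
            break
    return float(numerator / denom)


@dataclass(frozen=True)
class ParsimonyLimit:
    """The largest step count connectable at the given parsimony confidence."""

    limit: int
    confidence: float
    L_used: int


def connection_limit(L_used: int, confidence: float = 0.95) -> ParsimonyLimit:
    """Largest j with parsimony_probability(j, L_used) >= confidence."""
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    j = 0
    while 2 * (j + 1) < L_used:
        if parsimony_probability(j + 1, L_used) < confidence:
            break
        j += 1
    return ParsimonyLimit(limit=j, confidence=confidence, L_used=L_used)


@dataclass(frozen=True)
class HaplotypeNetwork:
    """Sampled haplotypes plus inferred intermediates, all edges length 1."""

    graph: nx.Graph

    @property
    def sampled_nodes(self) -> tuple[str, ...]:
        return tuple(n for n, d in self.graph.nodes(data=True) if not d["is_inferred"])

    @property
    def inferred_nodes(self) -> tuple[str, ...]:
        return tuple(n for n, d in self.graph.nodes(data=True) if d["is_inferred"])

    @property
    def components(self) -> tuple[frozenset, ...]:
        return tuple(frozenset(c) for c in nx.connected_components(self.graph))

    def path_length(self, a: str, b: str) -> int:
        return int(nx.shortest_path_length(self.graph, a, b))


def build_network(table: HaplotypeTable, limit: ParsimonyLimit | int) -> HaplotypeNetwork:
    """Agglomeratively link haplotypes within the parsimony connection limit.

    Candidate pairs are processed by ascending mutational distance; ties are
    broken by larger combined haplotype count (frequent haplotypes connect
    first), then lexicographic id pair. A pair is linked iff its distance is
    within the limit and it spans two components; a link of length j inserts
    j - 1 intermediate nodes (ids "mv1", "mv2", ...). Pairs whose endpoints
    are already connected are skipped, so the output is a forest of chains.
    """
    if table.n_haplotypes == 0:
        raise ValueError("empty haplotype table")
    lim = limit.limit if isinstance(limit, ParsimonyLimit) else int(limit)
    if lim < 1:
        raise ValueError("connection limit must be >= 1")

    g = nx.Graph()
    totals = table.total_counts
    for i, hap in enumerate(table.hap_ids):
        attrs = {f"count_{p}": int(table.counts[i, j]) for j, p in enumerate(table.populations)}
        g.add_node(hap, is_inferred=False, count=int(totals[i]), **attrs)

    candidates = [
        (int(table.dist[i, k]), -(int(totals[i] + totals[k])), (table.hap_ids[i], table.hap_ids[k]))
        for i, k in combinations(range(table.n_haplotypes), 2)
        if 1 <= table.dist[i, k] <= lim
    ]
    candidates.sort()

    comp = {hap: hap for hap in table.hap_ids}

    def find(x: str) -> str:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    mv_counter = 0
    for d, _, (a, b) in candidates:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        comp[ra] = rb
        chain = [a]
        for _ in range(d - 1):
            mv_counter += 1
            mv = f"mv{mv_counter}"
            g.add_node(mv, is_inferred=True, count=0)
            chain.append(mv)
        chain.append(b)
        for u, v in zip(chain, chain[1:]):
            g.add_edge(u, v)
    return HaplotypeNetwork(graph=g)


def export_network(net: HaplotypeNetwork, path, format: str = "graphml") -> None:
    """Write the network as graphml, gml, or a TSV edgelist.

    Node attributes (hap id, is_inferred flag, total and per-population
    counts) are preserved in graphml/gml; the edgelist carries topology only.
    """
    if format == "graphml":
        nx.write_graphml(net.graph, str(path))
    elif format == "gml":
        # GML keys must be alphanumeric: sanitise population-count attribute names
        g = nx.Graph()
        for n, data in net.graph.nodes(data=True):
            clean = {
                "".join(ch if ch.isalnum() else "_" for ch in k).strip("_"): v
                for k, v in data.items()
            }
            g.add_node(n, **clean)
        g.add_edges_from(net.graph.edges())
        nx.write_gml(g, str(path))
    elif format == "tsv-edgelist":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\n")
            for u, v in sorted(map(sorted, net.graph.edges())):
                fh.write(f"{u}\t{v}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
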