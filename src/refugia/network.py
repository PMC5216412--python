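"""Median-joining haplotype networks for multistate STR data.

Distances are summed absolute repeat differences.  The network starts from
the minimum-spanning network (the union of all minimum spanning trees, with
links up to ``epsilon`` steps beyond the minimum connection cost also kept)
and iteratively adds component-wise median vectors of node triplets
whenever doing so shortens the total spanning weight; obsolete medians
(degree below three) are pruned.  The procedure is deterministic: nodes are
ordered canonically (lexicographically by haplotype) before tie-breaking.

Median-joining is used rather than reduced-median: the reduced-median
construction is defined for binary characters, whereas STR loci are
multistate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import HaplotypeTable

__all__ = ["HaplotypeNetwork", "build_mj_network", "network_geography_summary"]


@dataclass
class HaplotypeNetwork:
    """Observed + inferred (median) haplotypes with stepwise-labelled edges.

    ``graph`` is a networkx Graph whose nodes are haplotype tuples; node
    attributes: ``multiplicity``, ``populations`` (Counter-style dict),
    ``is_median``; edge attributes: ``weight`` (total steps) and ``steps``
    (tuple of (locus, signed step count) pairs).
    """

    graph: nx.Graph
    loci: tuple
    n_excluded: int = 0

    @property
    def observed(self):
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def medians(self):
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def node_table(self) -> pd.DataFrame:
        rows = []
        for i, (node, d) in enumerate(sorted(self.graph.nodes(data=True))):
            rows.append(
                {
                    "id": i,
                    "haplotype": ",".join(map(str, node)),
                    "multiplicity": d["multiplicity"],
                    "is_median": d["is_median"],
                    "populations": ";".join(
                        f"{p}:{c}" for p, c in sorted(d["populations"].items())
                    ),
                }
            )
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            for locus, step in d["steps"]:
                rows.append(
                    {
                        "node1": ",".join(map(str, u)),
                        "node2": ",".join(map(str, v)),
                        "locus": locus,
                        "steps": step,
                    }
                )
        return pd.DataFrame(rows)


def _l1(a, b):
    return sum(abs(x - y) for x, y in zip(a, b))


def _msn_edges(nodes, epsilon):
    """Feasible links of the minimum-spanning network at tolerance epsilon.

    An edge of weight w is feasible when its endpoints lie in different
    components of the graph of feasible edges of weight < w - epsilon
    (epsilon = 0 gives the union of all minimum spanning trees).
    """
    idx = {n: i for i, n in enumerate(nodes)}
    edges = sorted(
        (_l1(u, v), u, v)
        for u, v in itertools.combinations(nodes, 2)
    )
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    feasible = []
    pending = []  # feasible edges not yet merged into the DSU
    for w, u, v in edges:
        while pending and pending[0][0] < w - epsilon:
            pw, pu, pv = pending.pop(0)
            ru, rv = find(idx[pu]), find(idx[pv])
            if ru != rv:
                parent[ru] = rv
        if find(idx[u]) != find(idx[v]):
            feasible.append((w, u, v))
            pending.append((w, u, v))
    return feasible


def _spanning_weight(nodes, epsilon):
    return sum(w for w, _, _ in _msn_edges(nodes, epsilon))


def _network_from_nodes(nodes, epsilon, loci):
    g = nx.Graph()
    for n in nodes:
        g.add_node(n)
    for w, u, v in _msn_edges(nodes, epsilon):
        steps = tuple(
            (loci[l], int(v[l] - u[l])) for l in range(len(loci)) if u[l] != v[l]
        )
        g.add_edge(u, v, weight=w, steps=steps)
    return g


def build_mj_network(table: HaplotypeTable, epsilon: int = 0,
                     max_median_rounds: int = 200) -> HaplotypeNetwork:
    """Median-joining network of the table's haplotypes.

    Haplotypes with any missing locus are excluded (count reported in
    ``n_excluded``).  Candidate medians are the component-wise medians of
    node triplets in which at least two pairs are currently linked; at each
    round the candidate giving the largest reduction in total spanning
    weight is added (ties broken lexicographically), until no candidate
    improves.  Medians that end with degree < 3 are pruned.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if len(table) == 0:
        raise ValueError("need at least one haplotype")
    complete = ~np.isnan(table.repeats).any(axis=1)
    n_excluded = int((~complete).sum())
    reps = table.repeats[complete].astype(int)
    pops = table.populations[complete]
    if len(reps) == 0:
        raise ValueError("all haplotypes have missing loci")

    mult: dict = {}
    popc: dict = {}
    for row, pop in zip(reps, pops):
        h = tuple(int(x) for x in row)
        mult[h] = mult.get(h, 0) + 1
        popc.setdefault(h, {})
        popc[h][pop] = popc[h].get(pop, 0) + 1

    observed = sorted(mult)
    nodes = list(observed)
    if len(nodes) > 1:
        for _ in range(max_median_rounds):
            g = _network_from_nodes(nodes, epsilon, table.loci)
            current = sum(d["weight"] for _, _, d in g.edges(data=True))
            node_set = set(nodes)
            candidates = set()
            for u, v in g.edges():
                for x in nodes:
                    if x is u or x is v:
                        continue
                    if g.has_edge(u, x) or g.has_edge(v, x):
                        m = tuple(
                            int(np.median([a, b, c]))
                            for a, b, c in zip(u, v, x)
                        )
                        if m not in node_set:
                            candidates.add(m)
            best = None
            for m in sorted(candidates):
                w = _spanning_weight(nodes + [m], epsilon)
                gain = current - w
                if gain > 0 and (best is None or gain > best[0]):
                    best = (gain, m)
            if best is None:
                break
            nodes.append(best[1])
            nodes.sort()
        # prune medians that never reached degree 3
        while True:
            g = _network_from_nodes(nodes, epsilon, table.loci)
            drop = [
                n for n in nodes
                if n not in mult and g.degree(n) < 3
            ]
            if not drop:
                break
            nodes = [n for n in nodes if n not in set(drop)]

    g = _network_from_nodes(nodes, epsilon, table.loci)
    for n in g.nodes:
        g.nodes[n]["is_median"] = n not in mult
        g.nodes[n]["multiplicity"] = mult.get(n, 0)
        g.nodes[n]["populations"] = popc.get(n, {})
    return HaplotypeNetwork(g, table.loci, n_excluded)


def network_geography_summary(net: HaplotypeNetwork, n_perm: int = 999,
                              seed: int = 0) -> dict:
    """Population assortativity of the network's edges.

    The statistic is the mean, over edges joining observed haplotypes, of
    the probability that random carriers of the two endpoints belong to the
    same population.  Significance comes from shuffling individual
    population labels (+1/+1 permutation p-value).  Degenerate networks
    (single population or no observed-observed edges) are flagged.
    """
    g = net.graph
    obs_edges = [
        (u, v) for u, v in g.edges()
        if not g.nodes[u]["is_median"] and not g.nodes[v]["is_median"]
    ]
    individuals = []
    node_members: dict = {}
    for n in net.observed:
        members = []
        for pop, c in g.nodes[n]["populations"].items():
            members.extend([pop] * c)
        node_members[n] = members
        individuals.extend(members)
    pops = sorted(set(individuals))
    if len(pops) < 2 or not obs_edges:
        return {
            "assortativity": np.nan,
            "p_value": np.nan,
            "degenerate": True,
            "node_composition": {
                n: dict(g.nodes[n]["populations"]) for n in net.observed
            },
        }

    def statistic(members_of):
        total = 0.0
        for u, v in obs_edges:
            mu, mv = members_of[u], members_of[v]
            same = sum(1 for a in mu for b in mv if a == b)
            total += same / (len(mu) * len(mv))
        return total / len(obs_edges)

    obs = statistic(node_members)
    rng = np.random.default_rng(seed)
    labels = np.array(individuals)
    sizes = [len(node_members[n]) for n in net.observed]
    hits = 0
    for _ in range(n_perm):
        shuffled = rng.permutation(labels)
        members_of = {}
        pos = 0
        for n, size in zip(net.observed, sizes):
            members_of[n] = list(shuffled[pos:pos + size])
            pos += size
        if statistic(members_of) >= obs - 1e-12:
            hits += 1
    return {
        "assortativity": float(obs),
        "p_value": (hits + 1) / (n_perm + 1),
        "degenerate": False,
        "node_composition": {
            n: dict(g.nodes[n]["populations"]) for n in net.observed
        },
    }
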