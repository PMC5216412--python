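"""Population-tree demographies with constant-then-exponential growth.

The model mirrors the splitting demography used for Y-STR expansion dating:
a single total effective (male) population size trajectory

    N(t) = N0_total * exp(-r t)   for t < beta   (backward time, generations)
    N(t) = N_a                    for t >= beta

with r = ln(N0_total / N_a) / beta, i.e. the population was constant at the
ancestral size ``N_a`` until ``beta`` generations ago and then grew
exponentially to the present total ``N0_total``.  Population splits divide
the total size among child populations: each branch of the population tree
carries a constant weight (fraction of the total), and weights of children
sum to the weight of their parent at every split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import skbio
import yaml

__all__ = ["PopTree", "DemographyModel", "TruthRecord"]


class PopTree:
    """Rooted binary-or-multifurcating population topology as flat arrays.

    Nodes are indexed 0..n_nodes-1 with terminals first (in newick tip
    order).  ``parent[root] == -1``.  Split times attach to internal nodes:
    the time at which the node's children merge into it (backward in time).
    """

    def __init__(self, newick: str):
        tree = skbio.TreeNode.read([newick])
        tips = list(tree.tips())
        if not tips:  # single-population tree, e.g. "A;"
            tips = [tree]
        tip_ids = {id(t) for t in tips}
        internals = [
            n for n in tree.postorder()
            if not n.is_tip() and id(n) not in tip_ids
        ]
        nodes = tips + internals
        self._skbio = tree
        self.labels = tuple(t.name for t in tips)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate population labels")
        index = {id(n): i for i, n in enumerate(nodes)}
        self.n_terminals = len(tips)
        self.n_nodes = len(nodes)
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.children = [[] for _ in range(self.n_nodes)]
        for n in nodes:
            if n.parent is not None:
                i, p = index[id(n)], index[id(n.parent)]
                self.parent[i] = p
                self.children[p].append(i)
        self.root = index[id(tree)]
        # clade (frozenset of tip labels) per node, for keying split times
        self.clades = [None] * self.n_nodes
        for i, n in enumerate(nodes):
            self.clades[i] = frozenset(
                t.name for t in (n.tips() if not n.is_tip() else [n])
            )

    def terminal_index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def internal_nodes(self):
        return [i for i in range(self.n_nodes) if self.children[i]]

    def lca(self, i: int, j: int) -> int:
        anc = set()
        k = i
        while k != -1:
            anc.add(k)
            k = self.parent[k]
        k = j
        while k not in anc:
            k = self.parent[k]
        return k


@dataclass
class DemographyModel:
    """A dated, sized population tree under SMM-mutating STR loci.

    Parameters
    ----------
    topology : str
        Newick string over population labels, e.g. ``"((A,B),(C,D));"``.
    n0 : dict
        Present-day effective size per terminal population (individuals;
        effective number of males for Y-chromosome data).
    n_ancestral : float
        Total effective size at and before the growth onset.
    growth_onset : float
        ``beta``: generations before present at which exponential growth
        began (0 means constant size, requiring ``n_ancestral == sum(n0)``).
    split_times : dict
        Split time in generations per internal node, keyed by the frozenset
        of terminal labels the node subtends.
    mutation_rate : float
        STR mutation rate per locus per generation (single-step model).
    generation_time : float
        Years per generation, used only when reporting in years/ka.
    """

    topology: str
    n0: dict
    n_ancestral: float
    growth_onset: float
    split_times: dict = field(default_factory=dict)
    mutation_rate: float = 6.9e-4
    generation_time: float = 28.9

    def __post_init__(self):
        self.tree = PopTree(self.topology)
        missing = set(self.tree.labels) - set(self.n0)
        if missing:
            raise ValueError(f"no present size for populations {missing}")
        if any(v < 1 for v in self.n0.values()) or self.n_ancestral < 1:
            raise ValueError("population sizes must be >= 1")
        if self.growth_onset < 0:
            raise ValueError("growth onset must be >= 0")
        self.split_times = {frozenset(k): float(v) for k, v in self.split_times.items()}
        # per-node split times / weights
        n = self.tree.n_nodes
        self.node_split = np.zeros(n)
        self.weights = np.zeros(n)
        total = float(sum(self.n0.values()))
        self.n0_total = total
        for i in range(n):
            clade = self.tree.clades[i]
            if self.tree.children[i]:
                try:
                    self.node_split[i] = self.split_times[clade]
                except KeyError:
                    raise ValueError(f"no split time for clade {set(clade)}") from None
            self.weights[i] = sum(self.n0[l] for l in clade) / total
        # split times strictly increase root-ward
        for i in self.tree.internal_nodes:
            p = self.tree.parent[i]
            if p != -1 and not self.node_split[i] < self.node_split[p]:
                raise ValueError("split times must strictly increase root-ward")
        if self.growth_onset == 0:
            if not np.isclose(self.n_ancestral, total):
                raise ValueError("growth_onset 0 requires n_ancestral == sum(n0)")
            self.growth_rate = 0.0
        else:
            self.growth_rate = float(np.log(total / self.n_ancestral)) / self.growth_onset

    # -- size trajectory ---------------------------------------------------

    def total_size(self, t):
        """Total effective size ``t`` generations before present."""
        t = np.asarray(t, dtype=float)
        return np.where(
            t < self.growth_onset,
            self.n0_total * np.exp(-self.growth_rate * t),
            self.n_ancestral,
        )

    def inv_size_integral(self, t1: float, t2: float) -> float:
        """``integral_{t1}^{t2} dt / N(t)`` (coalescent-time rescaling)."""
        if t2 < t1:
            raise ValueError("t2 < t1")
        b, r, n0 = self.growth_onset, self.growth_rate, self.n0_total
        total = 0.0
        lo, hi = t1, min(t2, b)
        if hi > lo:
            if r == 0:
                total += (hi - lo) / n0
            else:
                total += (np.exp(r * hi) - np.exp(r * lo)) / (n0 * r)
        lo, hi = max(t1, b), t2
        if hi > lo:
            total += (hi - lo) / self.n_ancestral
        return total

    def invert_inv_size_integral(self, t1: float, target: float) -> float:
        """Smallest ``t2 >= t1`` with ``inv_size_integral(t1, t2) == target``.

        Used to draw exact inhomogeneous coalescence times by time
        rescaling; returns ``inf`` never (the ancestral phase is constant,
        so any target is reachable)."""
        b, r, n0 = self.growth_onset, self.growth_rate, self.n0_total
        remain = target
        t = t1
        if t < b:
            if r == 0:
                cap = (b - t) / n0
                if remain <= cap:
                    return t + remain * n0
                remain -= cap
            else:
                cap = (np.exp(r * b) - np.exp(r * t)) / (n0 * r)
                if remain <= cap:
                    return np.log(np.exp(r * t) + remain * n0 * r) / r
                remain -= cap
            t = b
        return t + remain * self.n_ancestral

    # -- convenience constructors -----------------------------------------

    @classmethod
    def two_populations(cls, split_time, n0_per_pop=5000.0, n_ancestral=500.0,
                        growth_onset=400.0, mutation_rate=6.9e-4, **kw):
        return cls(
            "(A,B);",
            {"A": n0_per_pop, "B": n0_per_pop},
            n_ancestral,
            growth_onset,
            {frozenset({"A", "B"}): split_time},
            mutation_rate,
            **kw,
        )

    @classmethod
    def balanced_four(cls, t_ab, t_cd, t_root, n0_per_pop=2500.0,
                      n_ancestral=500.0, growth_onset=None,
                      mutation_rate=6.9e-4, **kw):
        if growth_onset is None:
            growth_onset = 1.25 * t_root
        return cls(
            "((A,B),(C,D));",
            {p: n0_per_pop for p in "ABCD"},
            n_ancestral,
            growth_onset,
            {
                frozenset({"A", "B"}): t_ab,
                frozenset({"C", "D"}): t_cd,
                frozenset("ABCD"): t_root,
            },
            mutation_rate,
            **kw,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "topology": self.topology,
                "n0": {k: float(v) for k, v in self.n0.items()},
                "n_ancestral": float(self.n_ancestral),
                "growth_onset": float(self.growth_onset),
                "split_times": {
                    ",".join(sorted(k)): float(v) for k, v in self.split_times.items()
                },
                "mutation_rate": float(self.mutation_rate),
                "generation_time": float(self.generation_time),
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text_or_path) -> "DemographyModel":
        from pathlib import Path

        if isinstance(text_or_path, Path):
            data = yaml.safe_load(text_or_path.read_text())
        elif isinstance(text_or_path, str) and "\n" not in text_or_path \
                and text_or_path.endswith((".yml", ".yaml")):
            with open(text_or_path) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(text_or_path)
        data["split_times"] = {
            frozenset(k.split(",")): v for k, v in data.get("split_times", {}).items()
        }
        return cls(**data)


@dataclass
class TruthRecord:
    """Ground truth attached to one simulated dataset."""

    tmrca: float
    split_times: dict
    uep_tmrcas: dict
    seed: int

    def __post_init__(self):
        for name, t in self.uep_tmrcas.items():
            if t > self.tmrca + 1e-9:
                raise ValueError(f"UEP clade {name} older than sample TMRCA")

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "tmrca": float(self.tmrca),
                "split_times": {
                    ",".join(sorted(k)): float(v) for k, v in self.split_times.items()
                },
                "uep_tmrcas": {k: float(v) for k, v in self.uep_tmrcas.items()},
                "seed": int(self.seed),
            },
            sort_keys=False,
        )
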