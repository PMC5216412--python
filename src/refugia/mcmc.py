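"""Bayesian MCMC for Y-STR TMRCAs and population split times.

A Metropolis-Hastings sampler over STR genealogies and demographic
parameters in the style of BATWING: single-step mutation at each locus,
coalescence governed by a total effective size that was constant at ``N_a``
until ``beta`` generations ago and then grew exponentially to the present
total ``N0``, and population splitting that divides the total size among
child populations according to per-split proportions.  The population-tree
topology is fixed per run; the genealogy, its node times, the mutation rate
and the demographic parameters are sampled.

The likelihood is computed by Felsenstein pruning over a truncated window
of integer repeat states (uniform root prior over the window), rather than
by augmenting the genealogy with mutation events; the target distribution
is the same and two-tip cases reduce to the closed-form Skellam transition
probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from . import _engine
from .demography import DemographyModel, PopTree
from .io import HaplotypeTable
from .simulate import simulate_genealogy

__all__ = [
    "Prior",
    "PriorSpec",
    "PosteriorSummary",
    "run_mcmc",
    "uep_tmrca",
    "tree_log_likelihood",
    "coalescent_log_prior",
    "effective_sample_size",
]


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prior:
    """One prior distribution: ``gamma(shape, mean)``, ``lognormal(meanlog,
    sdlog)``, ``uniform(lo, hi)``, ``beta(a, b)`` or ``fixed(value)``."""

    kind: str
    a: float
    b: float = 0.0

    def __post_init__(self):
        if self.kind not in ("gamma", "lognormal", "uniform", "beta", "fixed"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind in ("gamma", "beta") and (self.a <= 0 or self.b <= 0):
            raise ValueError("hyperparameters must be strictly positive")

    @property
    def fixed(self):
        return self.kind == "fixed"

    def _frozen(self):
        if self.kind == "gamma":
            return scipy.stats.gamma(self.a, scale=self.b / self.a)
        if self.kind == "lognormal":
            return scipy.stats.lognorm(self.b, scale=np.exp(self.a))
        if self.kind == "uniform":
            return scipy.stats.uniform(self.a, self.b - self.a)
        if self.kind == "beta":
            return scipy.stats.beta(self.a, self.b)
        raise ValueError("fixed prior has no distribution")

    def logpdf(self, x):
        # closed forms: this sits on the MCMC hot path
        if self.fixed:
            return 0.0
        if self.kind == "gamma":
            if x <= 0:
                return -np.inf
            scale = self.b / self.a
            return float(
                (self.a - 1) * np.log(x) - x / scale
                - self.a * np.log(scale) - scipy.special.gammaln(self.a)
            )
        if self.kind == "lognormal":
            if x <= 0:
                return -np.inf
            z = (np.log(x) - self.a) / self.b
            return float(
                -np.log(x) - np.log(self.b) - 0.5 * np.log(2 * np.pi)
                - 0.5 * z * z
            )
        if self.kind == "uniform":
            if not (self.a <= x <= self.b):
                return -np.inf
            return float(-np.log(self.b - self.a))
        # beta
        if not (0 < x < 1):
            return -np.inf
        return float(
            (self.a - 1) * np.log(x) + (self.b - 1) * np.log1p(-x)
            - scipy.special.betaln(self.a, self.b)
        )

    def cdf(self, x):
        return self._frozen().cdf(x)

    def median(self):
        return self.a if self.fixed else float(self._frozen().median())

    def support(self):
        if self.kind == "uniform":
            return self.a, self.b
        if self.kind == "beta":
            return 0.0, 1.0
        if self.kind == "fixed":
            return self.a, self.a
        return 0.0, np.inf


@dataclass
class PriorSpec:
    """Priors for the sampled parameters.

    Defaults: per-locus mutation rate ~ Gamma(shape 2, mean 6.9e-4); total
    present size N0 ~ Gamma(shape 1, mean 5000); growth rate ~ LogNormal
    (median 2e-3, sdlog 1); growth onset beta ~ Uniform(0, 5000)
    generations; split proportions ~ Beta(1, 1); split times ~ Uniform(0,
    5000) generations.
    """

    mu: Prior = field(default_factory=lambda: Prior("gamma", 2.0, 6.9e-4))
    n0: Prior = field(default_factory=lambda: Prior("gamma", 1.0, 5000.0))
    growth: Prior = field(default_factory=lambda: Prior("lognormal", np.log(2e-3), 1.0))
    beta: Prior = field(default_factory=lambda: Prior("uniform", 0.0, 5000.0))
    split_prop: Prior = field(default_factory=lambda: Prior("beta", 1.0, 1.0))
    split_time: Prior = field(default_factory=lambda: Prior("uniform", 0.0, 5000.0))


@dataclass
class PosteriorSummary:
    """Median, central 95% interval and ESS per reported quantity."""

    quantities: dict
    acceptance: dict
    n_samples: int

    def median(self, name):
        return self.quantities[name]["median"]

    def interval(self, name):
        q = self.quantities[name]
        return q["q025"], q["q975"]

    def __repr__(self):
        lines = [f"PosteriorSummary({self.n_samples} samples)"]
        for name, q in self.quantities.items():
            lines.append(
                f"  {name}: median={q['median']:.4g} "
                f"95% CI=[{q['q025']:.4g}, {q['q975']:.4g}] ess={q['ess']:.0f}"
            )
        return "\n".join(lines)


def effective_sample_size(x) -> float:
    """ESS via the initial positive sequence of autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
    # Geyer initial positive sequence over pairs
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k]
        if pair < 0:
            break
        s += pair
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), n))


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

class StrMCMC:
    """Sampler state and moves for one dataset / population topology."""

    def __init__(self, table: HaplotypeTable, priors: PriorSpec,
                 topology: str | None = None, seed: int = 0,
                 window_margin: int = 12):
        self.table = table
        self.priors = priors
        self.rng = np.random.default_rng(seed)
        self.seed = int(seed)
        self.n_tips = len(table)
        if self.n_tips < 2:
            raise ValueError("need at least two haplotypes")
        self.L = table.n_loci

        # population structure -------------------------------------------
        pops = table.populations
        if topology is None:
            self.topology = None
            self.pop_labels = ("ALL",)
            self.pop_parent = np.array([-1], dtype=np.int64)
            self.pop_depth = np.array([0], dtype=np.int64)
            self.pop_children = [[]]
            self.split_nodes = np.empty(0, dtype=np.int64)
            self.tip_branch = np.zeros(self.n_tips, dtype=np.int64)
            self.n_pop_nodes = 1
        else:
            ptree = PopTree(topology)
            self.topology = topology
            self.pop_labels = ptree.labels
            missing = set(ptree.labels) - set(pops)
            if missing:
                raise ValueError(f"populations {missing} absent from table")
            extra = set(pops) - set(ptree.labels)
            if extra:
                raise ValueError(f"populations {extra} not in topology")
            self.pop_parent = ptree.parent.copy()
            self.pop_children = ptree.children
            self.n_pop_nodes = ptree.n_nodes
            for i in ptree.internal_nodes:
                if len(ptree.children[i]) != 2:
                    raise ValueError("population topology must be binary")
            self.pop_depth = np.zeros(self.n_pop_nodes, dtype=np.int64)
            for i in range(self.n_pop_nodes):
                d, k = 0, i
                while self.pop_parent[k] != -1:
                    k = self.pop_parent[k]
                    d += 1
                self.pop_depth[i] = d
            self.split_nodes = np.array(ptree.internal_nodes, dtype=np.int64)
            label_ix = {l: i for i, l in enumerate(ptree.labels)}
            self.tip_branch = np.array([label_ix[p] for p in pops], dtype=np.int64)
            self._ptree = ptree

        # parameters -------------------------------------------------------
        self.mu = priors.mu.median()
        self.n0_tot = priors.n0.median()
        self.growth = 0.0 if priors.growth.fixed and priors.growth.a == 0 \
            else priors.growth.median()
        self.beta = priors.beta.median()
        n_splits = len(self.split_nodes)
        self.split_props = np.full(n_splits, 0.5)
        if priors.split_prop.fixed:
            self.split_props[:] = priors.split_prop.a
        self.pop_lower = np.zeros(self.n_pop_nodes)
        self._init_split_times()
        self.pop_weight = np.ones(self.n_pop_nodes)
        self._update_weights()

        # window / tip states ---------------------------------------------
        margin = int(window_margin)
        if self.L > 0:
            lo = np.nanmin(table.repeats, axis=0)
            hi = np.nanmax(table.repeats, axis=0)
            lo[np.isnan(lo)] = 14
            hi[np.isnan(hi)] = 14
            width = int(np.max(hi - lo)) + 2 * margin + 1
            self.W = width
            self.offsets = (lo - margin).astype(np.int64)
            st = np.full((self.n_tips, self.L), -1, dtype=np.int64)
            for l in range(self.L):
                col = table.repeats[:, l]
                ok = ~np.isnan(col)
                st[ok, l] = col[ok].astype(np.int64) - self.offsets[l]
            self.tipstates = st
        else:
            self.W = 1
            self.offsets = np.empty(0, dtype=np.int64)
            self.tipstates = np.empty((self.n_tips, 0), dtype=np.int64)

        # genealogy + buffers ---------------------------------------------
        self._init_genealogy()
        n_nodes = 2 * self.n_tips - 1
        shape = (n_nodes, self.L, self.W)
        self.partials = np.zeros(shape)
        self.logscale = np.zeros((n_nodes, self.L))
        self.kernels = np.zeros((n_nodes, self.W))
        self.sups = np.ones(n_nodes, dtype=np.int64)
        self._alt = {
            "partials": np.zeros(shape),
            "logscale": np.zeros((n_nodes, self.L)),
            "kernels": np.zeros((n_nodes, self.W)),
            "sups": np.ones(n_nodes, dtype=np.int64),
        }
        self._pbuf = np.zeros((n_nodes, self.L, self.W))
        self._lsbuf = np.zeros((n_nodes, self.L))
        self._kbuf = np.zeros((3, self.W))
        self._supbuf = np.zeros(3, dtype=np.int64)
        self._path = np.zeros(n_nodes, dtype=np.int64)
        self._msg = np.zeros((2, self.W))

        self.node_lca = np.zeros(n_nodes, dtype=np.int64)
        self._refresh_postorder()
        _engine.update_node_lca(self.postorder, self.left, self.right,
                                self.n_tips, self.tip_branch,
                                self.pop_parent, self.pop_depth, self.node_lca)
        self.loglik = self._full_likelihood_main()
        self.logprior = self._coal_logprior(self.times)
        if not np.isfinite(self.loglik) or not np.isfinite(self.logprior):
            raise RuntimeError("invalid initial state")
        self.accept_counts = {}
        self.attempt_counts = {}

    # -- initialisation ----------------------------------------------------

    def _init_split_times(self):
        lo, hi = self.priors.split_time.support()
        if len(self.split_nodes) == 0:
            return
        # start low: split times rise easily against the genealogy but can
        # only descend in lock-step with its inter-population node times
        base = lo + 0.01 * (hi - lo)
        for j, node in enumerate(self.split_nodes):
            child_max = 0.0
            for c in self.pop_children[node]:
                child_max = max(child_max, self.pop_lower[c])
            self.pop_lower[node] = min(child_max * 1.6 + base, hi * 0.95)
        # strict ordering sanity
        for node in self.split_nodes:
            p = self.pop_parent[node]
            if p != -1 and not self.pop_lower[node] < self.pop_lower[p]:
                raise RuntimeError("could not initialise ordered split times")

    def _update_weights(self):
        order = sorted(range(self.n_pop_nodes),
                       key=lambda i: self.pop_depth[i])
        for i in order:
            p = self.pop_parent[i]
            if p == -1:
                self.pop_weight[i] = 1.0
            else:
                j = int(np.where(self.split_nodes == p)[0][0])
                frac = self.split_props[j]
                first = self.pop_children[p][0]
                self.pop_weight[i] = self.pop_weight[p] * (
                    frac if i == first else 1.0 - frac
                )

    def _demography(self) -> DemographyModel:
        n_anc = self.n0_tot * np.exp(-self.growth * self.beta)
        if self.topology is None:
            return DemographyModel(
                "ALL;", {"ALL": self.n0_tot}, max(n_anc, 1.0),
                self.beta if self.growth > 0 else 0.0,
                {}, self.mu,
            )
        splits = {}
        for node in self.split_nodes:
            splits[self._ptree.clades[node]] = self.pop_lower[node]
        n0 = {
            lab: self.n0_tot * self.pop_weight[i]
            for i, lab in enumerate(self.pop_labels)
        }
        return DemographyModel(
            self.topology, n0, max(n_anc, 1.0),
            self.beta if self.growth > 0 else 0.0, splits, self.mu,
        )

    def _init_genealogy(self):
        pops = self.table.populations
        if self.topology is None:
            counts = {"ALL": self.n_tips}
        else:
            counts = {
                lab: int(np.sum(pops == lab)) for lab in self.pop_labels
            }
        times, parent, tip_pops = simulate_genealogy(
            self._demography(), counts, self.rng
        )
        n = self.n_tips
        # simulate_genealogy groups tips by population; remap to table rows
        perm = np.empty(n, dtype=np.int64)  # sim tip -> table row
        cursor = 0
        for b_ix, lab in enumerate(self.pop_labels):
            rows = (
                np.arange(n)
                if self.topology is None
                else np.where(pops == lab)[0]
            )
            for r in rows:
                perm[cursor] = r
                cursor += 1
        remap = np.arange(len(times))
        remap[:n] = perm
        self.times = np.zeros(len(times))
        self.times[remap] = times
        self.parent = np.full(len(times), -1, dtype=np.int64)
        for i, p in enumerate(parent):
            if p != -1:
                self.parent[remap[i]] = remap[p]
        self._rebuild_children()

    def _rebuild_children(self):
        n_nodes = 2 * self.n_tips - 1
        self.left = np.full(n_nodes, -1, dtype=np.int64)
        self.right = np.full(n_nodes, -1, dtype=np.int64)
        for i in range(n_nodes):
            p = self.parent[i]
            if p != -1:
                if self.left[p] == -1:
                    self.left[p] = i
                else:
                    self.right[p] = i

    def _refresh_postorder(self):
        n_nodes = 2 * self.n_tips - 1
        root = int(np.where(self.parent == -1)[0][0])
        self.root = root
        order = []
        stack = [(root, False)]
        while stack:
            node, done = stack.pop()
            if node < self.n_tips:
                continue
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                stack.append((self.left[node], False))
                stack.append((self.right[node], False))
        self.postorder = np.array(order, dtype=np.int64)

    # -- densities ---------------------------------------------------------

    def _full_likelihood_main(self):
        return _engine.full_likelihood(
            self.times, self.parent, self.left, self.right, self.n_tips,
            self.postorder, self.tipstates, self.partials, self.logscale,
            self.kernels, self.sups, self.W, self.L, self.mu, self._msg,
        )

    def _full_likelihood_alt(self, times, parent, left, right, postorder, mu):
        a = self._alt
        return _engine.full_likelihood(
            times, parent, left, right, self.n_tips, postorder,
            self.tipstates, a["partials"], a["logscale"], a["kernels"],
            a["sups"], self.W, self.L, mu, self._msg,
        )

    def _swap_alt(self):
        for key in ("partials", "logscale", "kernels", "sups"):
            main = getattr(self, key)
            setattr(self, key, self._alt[key])
            self._alt[key] = main

    def _coal_logprior(self, times, node_lca=None, pop_lower=None,
                       pop_weight=None, n0=None, growth=None, beta=None):
        return _engine.coal_logprior(
            times, self.n_tips,
            self.node_lca if node_lca is None else node_lca,
            self.tip_branch, self.pop_parent,
            self.pop_lower if pop_lower is None else pop_lower,
            self.pop_weight if pop_weight is None else pop_weight,
            self.n_pop_nodes, self.split_nodes,
            self.n0_tot if n0 is None else n0,
            self.growth if growth is None else growth,
            self.beta if beta is None else beta,
        )

    def _hyper_logprior(self, mu=None, n0=None, growth=None, beta=None,
                        pop_lower=None, props=None):
        pr = self.priors
        mu = self.mu if mu is None else mu
        n0 = self.n0_tot if n0 is None else n0
        growth = self.growth if growth is None else growth
        beta = self.beta if beta is None else beta
        pop_lower = self.pop_lower if pop_lower is None else pop_lower
        props = self.split_props if props is None else props
        total = (
            pr.mu.logpdf(mu) + pr.n0.logpdf(n0)
            + pr.growth.logpdf(growth) + pr.beta.logpdf(beta)
        )
        lo, hi = pr.split_time.support()
        for j, node in enumerate(self.split_nodes):
            s = pop_lower[node]
            if not (lo <= s <= hi):
                return -np.inf
            p = self.pop_parent[node]
            if p != -1 and not s < pop_lower[p]:
                return -np.inf
            total += pr.split_time.logpdf(s) + pr.split_prop.logpdf(props[j])
        return total

    # -- moves -------------------------------------------------------------

    def _record(self, name, accepted):
        self.attempt_counts[name] = self.attempt_counts.get(name, 0) + 1
        if accepted:
            self.accept_counts[name] = self.accept_counts.get(name, 0) + 1

    def _move_node_times(self):
        ll, lp, acc, att = _engine.sweep_node_times(
            self.times, self.parent, self.left, self.right, self.n_tips,
            self.tipstates, self.partials, self.logscale, self.kernels,
            self.sups, self.W, self.L, self.mu, self.loglik, self.logprior,
            self.node_lca, self.tip_branch, self.pop_parent, self.pop_lower,
            self.pop_weight, self.n_pop_nodes, self.split_nodes,
            self.n0_tot, self.growth, self.beta, 0.7,
            self._pbuf, self._lsbuf, self._kbuf, self._supbuf, self._path,
            self._msg,
        )
        self.loglik, self.logprior = ll, lp
        self.attempt_counts["node_time"] = (
            self.attempt_counts.get("node_time", 0) + att
        )
        self.accept_counts["node_time"] = (
            self.accept_counts.get("node_time", 0) + acc
        )

    def _move_spr(self):
        n = self.n_tips
        n_nodes = 2 * n - 1
        cand_v = [
            v for v in range(n_nodes)
            if self.parent[v] != -1 and self.parent[self.parent[v]] != -1
        ]
        if not cand_v:
            return
        v = int(self.rng.choice(cand_v))
        u = self.parent[v]
        g = self.parent[u]
        s = self.left[u] if self.right[u] == v else self.right[u]
        t_u = self.times[u]
        # subtree of v
        in_sub = np.zeros(n_nodes, dtype=bool)
        stack = [v]
        while stack:
            x = stack.pop()
            in_sub[x] = True
            if x >= n:
                stack.extend((self.left[x], self.right[x]))
        cands = [
            x for x in range(n_nodes)
            if not in_sub[x] and x != u and self.parent[x] != -1
            and self.times[x] < t_u < self.times[self.parent[x]]
        ]
        # s qualifies after detachment (its edge extends to g)
        if s not in cands and self.times[s] < t_u < self.times[g]:
            cands.append(s)
        if not cands:
            return
        x = int(self.rng.choice(cands))
        self._record("spr", False)
        if x == s:  # identity reattachment
            self.attempt_counts["spr"] -= 1
            return
        parent = self.parent.copy()
        left = self.left.copy()
        right = self.right.copy()
        # detach u: replace u by s under g
        if left[g] == u:
            left[g] = s
        else:
            right[g] = s
        parent[s] = g
        # insert u on edge (x, px)
        px = parent[x]
        if left[px] == x:
            left[px] = u
        else:
            right[px] = u
        parent[u] = px
        left[u], right[u] = v, x
        parent[x] = u
        # postorder + lca for trial topology
        post = self._postorder_of(parent, left, right)
        lca = np.zeros(n_nodes, dtype=np.int64)
        _engine.update_node_lca(post, left, right, n, self.tip_branch,
                                self.pop_parent, self.pop_depth, lca)
        new_lp = self._coal_logprior(self.times, node_lca=lca)
        if not np.isfinite(new_lp):
            return
        new_ll = self._full_likelihood_alt(
            self.times, parent, left, right, post, self.mu
        )
        dlog = (new_ll - self.loglik) + (new_lp - self.logprior)
        if dlog >= 0 or np.log(self.rng.random()) < dlog:
            self.parent, self.left, self.right = parent, left, right
            self.postorder = post
            self.node_lca = lca
            self.root = post[-1]
            self._swap_alt()
            self.loglik, self.logprior = new_ll, new_lp
            self._record("spr", True)
            self.attempt_counts["spr"] -= 1

    def _postorder_of(self, parent, left, right):
        root = int(np.where(parent == -1)[0][0])
        order = []
        stack = [(root, False)]
        while stack:
            node, done = stack.pop()
            if node < self.n_tips:
                continue
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                stack.append((left[node], False))
                stack.append((right[node], False))
        return np.array(order, dtype=np.int64)

    def _move_scale(self):
        u = (self.rng.random() * 2 - 1) * 0.12
        c = np.exp(u)
        times = self.times.copy()
        times[self.n_tips:] *= c
        pop_lower = self.pop_lower * c
        n_scaled = (self.n_tips - 1) + len(self.split_nodes)
        new_hp = self._hyper_logprior(pop_lower=pop_lower)
        if not np.isfinite(new_hp):
            self._record("scale", False)
            return
        new_lp = self._coal_logprior(times, pop_lower=pop_lower)
        if not np.isfinite(new_lp):
            self._record("scale", False)
            return
        new_ll = self._full_likelihood_alt(
            times, self.parent, self.left, self.right, self.postorder, self.mu
        )
        cur_hp = self._hyper_logprior()
        dlog = (
            (new_ll - self.loglik) + (new_lp - self.logprior)
            + (new_hp - cur_hp) + n_scaled * u
        )
        ok = dlog >= 0 or np.log(self.rng.random()) < dlog
        if ok:
            self.times = times
            self.pop_lower = pop_lower
            self._swap_alt()
            self.loglik, self.logprior = new_ll, new_lp
        self._record("scale", ok)

    def _move_ridge(self):
        """Scale all internal times and split times by c and mu by 1/c.

        Every branch's expected mutation count mu*len is unchanged, so the
        likelihood is exactly invariant; only the priors and the Jacobian
        enter the acceptance ratio.  This traverses the mu-time ridge that
        defeats single-parameter moves.
        """
        if self.priors.mu.fixed:
            return
        u = (self.rng.random() * 2 - 1) * 0.4
        c = np.exp(u)
        times = self.times.copy()
        times[self.n_tips:] *= c
        pop_lower = self.pop_lower * c
        mu_new = self.mu / c
        new_hp = self._hyper_logprior(mu=mu_new, pop_lower=pop_lower)
        if not np.isfinite(new_hp):
            self._record("ridge", False)
            return
        new_lp = self._coal_logprior(times, pop_lower=pop_lower)
        cur_hp = self._hyper_logprior()
        n_scaled = (self.n_tips - 1) + len(self.split_nodes) - 1
        dlog = (new_lp - self.logprior) + (new_hp - cur_hp) + n_scaled * u
        ok = np.isfinite(new_lp) and (
            dlog >= 0 or np.log(self.rng.random()) < dlog
        )
        if ok:
            self.times = times
            self.pop_lower = pop_lower
            self.mu = mu_new
            self.logprior = new_lp
            # theta per branch unchanged: kernels and partials remain valid
        self._record("ridge", ok)

    def _move_rescale_all(self):
        """Rescale the whole configuration's time axis: internal times,
        split times, growth onset and N0 multiplied by c; growth rate and
        mu divided by c.  Branch thetas are unchanged, so the likelihood is
        exactly invariant; the coalescent prior and hyperpriors move."""
        pr = self.priors
        if pr.mu.fixed or pr.n0.fixed or pr.growth.fixed or pr.beta.fixed:
            return
        u = (self.rng.random() * 2 - 1) * 0.5
        c = np.exp(u)
        times = self.times.copy()
        times[self.n_tips:] *= c
        pop_lower = self.pop_lower * c
        mu_new = self.mu / c
        n0_new = self.n0_tot * c
        growth_new = self.growth / c
        beta_new = self.beta * c
        new_hp = self._hyper_logprior(mu=mu_new, n0=n0_new, growth=growth_new,
                                      beta=beta_new, pop_lower=pop_lower)
        if not np.isfinite(new_hp):
            self._record("rescale_all", False)
            return
        new_lp = self._coal_logprior(times, pop_lower=pop_lower, n0=n0_new,
                                     growth=growth_new, beta=beta_new)
        cur_hp = self._hyper_logprior()
        # Jacobian: +1 per multiplied quantity, -1 per divided one
        n_jac = (self.n_tips - 1) + len(self.split_nodes) + 2 - 2
        dlog = (new_lp - self.logprior) + (new_hp - cur_hp) + n_jac * u
        ok = np.isfinite(new_lp) and (
            dlog >= 0 or np.log(self.rng.random()) < dlog
        )
        if ok:
            self.times = times
            self.pop_lower = pop_lower
            self.mu = mu_new
            self.n0_tot = n0_new
            self.growth = growth_new
            self.beta = beta_new
            self.logprior = new_lp
        self._record("rescale_all", ok)

    def _move_mu(self):
        if self.priors.mu.fixed:
            return
        u = self.rng.normal(0.0, 0.25)
        mu_new = self.mu * np.exp(u)
        new_ll = self._full_likelihood_alt(
            self.times, self.parent, self.left, self.right,
            self.postorder, mu_new
        )
        dlog = (
            (new_ll - self.loglik)
            + (self.priors.mu.logpdf(mu_new) - self.priors.mu.logpdf(self.mu))
            + u  # log-scale proposal Jacobian
        )
        ok = np.isfinite(new_ll) and (
            dlog >= 0 or np.log(self.rng.random()) < dlog
        )
        if ok:
            self.mu = mu_new
            self._swap_alt()
            self.loglik = new_ll
        self._record("mu", ok)

    def _propose_scalar(self, prior: Prior, cur, step):
        """Propose under a generic prior; returns (value, log Jacobian)."""
        if prior.kind == "uniform":
            lo, hi = prior.support()
            span = (hi - lo) * step
            x = cur + self.rng.uniform(-span, span)
            while x < lo or x > hi:  # reflect
                if x < lo:
                    x = 2 * lo - x
                if x > hi:
                    x = 2 * hi - x
            return x, 0.0
        u = self.rng.normal(0.0, step)
        return cur * np.exp(u), u

    def _move_demography(self):
        pr = self.priors
        for name, prior, step in (
            ("n0", pr.n0, 0.25), ("growth", pr.growth, 0.3),
            ("beta", pr.beta, 0.15),
        ):
            if prior.fixed:
                continue
            cur = getattr(self, {"n0": "n0_tot"}.get(name, name))
            new, jac = self._propose_scalar(prior, cur, step)
            kw = {("n0" if name == "n0" else name): new}
            new_hp = self._hyper_logprior(**kw)
            if np.isfinite(new_hp):
                new_lp = self._coal_logprior(self.times, **kw)
                cur_hp = self._hyper_logprior()
                dlog = (new_lp - self.logprior) + (new_hp - cur_hp) + jac
                ok = np.isfinite(new_lp) and (
                    dlog >= 0 or np.log(self.rng.random()) < dlog
                )
            else:
                ok = False
            if ok:
                setattr(self, {"n0": "n0_tot"}.get(name, name), new)
                self.logprior = new_lp
            self._record(name, ok)

    def _move_splits(self):
        pr = self.priors
        lo_s, hi_s = pr.split_time.support()
        internal_lca = self.node_lca[self.n_tips:]
        internal_times = self.times[self.n_tips:]
        for j, node in enumerate(self.split_nodes):
            if not pr.split_time.fixed:
                lo = lo_s
                for c in self.pop_children[node]:
                    lo = max(lo, self.pop_lower[c])
                hi = hi_s
                p = self.pop_parent[node]
                if p != -1:
                    hi = min(hi, self.pop_lower[p])
                # genealogy constraint: coalescences spanning this split
                spanning = internal_times[internal_lca == node]
                if spanning.size:
                    hi = min(hi, float(spanning.min()))
                if hi > lo:
                    new = self.rng.uniform(lo, hi)
                    pop_lower = self.pop_lower.copy()
                    pop_lower[node] = new
                    new_lp = self._coal_logprior(self.times, pop_lower=pop_lower)
                    dlog = new_lp - self.logprior
                    ok = np.isfinite(new_lp) and (
                        dlog >= 0 or np.log(self.rng.random()) < dlog
                    )
                    if ok:
                        self.pop_lower = pop_lower
                        self.logprior = new_lp
                    self._record("split_time", ok)
            if not pr.split_prop.fixed:
                cur = self.split_props[j]
                new = cur + self.rng.uniform(-0.15, 0.15)
                while new < 0 or new > 1:
                    if new < 0:
                        new = -new
                    if new > 1:
                        new = 2 - new
                if 0 < new < 1:
                    props = self.split_props.copy()
                    props[j] = new
                    weight_save = self.pop_weight.copy()
                    props_save = self.split_props
                    self.split_props = props
                    self._update_weights()
                    new_lp = self._coal_logprior(self.times)
                    dhp = (
                        pr.split_prop.logpdf(new) - pr.split_prop.logpdf(cur)
                    )
                    dlog = (new_lp - self.logprior) + dhp
                    ok = np.isfinite(new_lp) and (
                        dlog >= 0 or np.log(self.rng.random()) < dlog
                    )
                    if ok:
                        self.logprior = new_lp
                    else:
                        self.split_props = props_save
                        self.pop_weight = weight_save
                    self._record("split_prop", ok)

    # -- main loop ----------------------------------------------------------

    def run(self, n_iter: int, burn_in: int, thin: int = 1,
            n_spr: int | None = None) -> tuple:
        """Run the chain; returns (PosteriorSummary, trace DataFrame)."""
        if n_iter <= burn_in:
            raise ValueError("n_iter must exceed burn_in")
        _engine.seed_rng(int(self.rng.integers(2**31 - 1)))
        if n_spr is None:
            n_spr = max(1, self.n_tips // 8)
        rows = []
        for it in range(n_iter):
            self._move_node_times()
            for _ in range(n_spr):
                self._move_spr()
            self._move_scale()
            self._move_mu()
            # ridge/demographic moves are prior-only and cheap: repeat
            for _ in range(3):
                self._move_ridge()
                self._move_rescale_all()
                self._move_demography()
                self._move_splits()
            if it >= burn_in and (it - burn_in) % thin == 0:
                row = {
                    "iteration": it,
                    "logpost": self.loglik + self.logprior,
                    "loglik": self.loglik,
                    "mu": self.mu,
                    "n0": self.n0_tot,
                    "growth_rate": self.growth,
                    "growth_onset": self.beta,
                    "n_ancestral": self.n0_tot * np.exp(-self.growth * self.beta),
                    "tmrca": self.times[self.root],
                }
                for node in self.split_nodes:
                    key = "split_" + ",".join(sorted(self._ptree.clades[node]))
                    row[key] = self.pop_lower[node]
                rows.append(row)
        trace = pd.DataFrame(rows)
        acceptance = {
            k: self.accept_counts.get(k, 0) / max(v, 1)
            for k, v in self.attempt_counts.items()
        }
        low = {k: r for k, r in acceptance.items() if r < 0.005}
        if low:
            warnings.warn(
                f"acceptance rates below 0.5% after burn-in: {low}; "
                "the chain may not be mixing"
            )
        skip = {"iteration"}
        quantities = {}
        for col in trace.columns:
            if col in skip:
                continue
            x = trace[col].to_numpy()
            quantities[col] = {
                "median": float(np.median(x)),
                "q025": float(np.quantile(x, 0.025)),
                "q975": float(np.quantile(x, 0.975)),
                "ess": effective_sample_size(x),
            }
        return PosteriorSummary(quantities, acceptance, len(trace)), trace


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def run_mcmc(table: HaplotypeTable, priors: PriorSpec | None = None,
             topology: str | None = None, n_iter: int = 2000,
             burn_in: int = 500, thin: int = 2, seed: int = 0,
             n_spr: int | None = None, **kwargs):
    """Fit the splitting-coalescent SMM model to an STR haplotype table.

    ``topology`` is a Newick string over the table's population labels (or
    None to treat the sample as a single panmictic population).  Returns
    ``(PosteriorSummary, trace)``; identical seeds give identical traces.
    """
    chain = StrMCMC(table, priors or PriorSpec(), topology=topology,
                    seed=seed, **kwargs)
    return chain.run(n_iter, burn_in, thin, n_spr=n_spr)


def uep_tmrca(table: HaplotypeTable, carriers, priors: PriorSpec | None = None,
              n_iter: int = 2000, burn_in: int = 500, thin: int = 2,
              seed: int = 0, **kwargs):
    """TMRCA of the carriers of one UEP (haplogroup-defining marker).

    Runs the single-population sampler on the carrier subset; carrier
    monophyly holds by construction of the subset analysis, which
    approximates full conditioning on a unique mutation event.
    """
    carriers = np.asarray(carriers)
    sub = table.subset(carriers)
    if len(sub) == 0:
        raise ValueError("carrier set is empty")
    if len(sub) == 1:
        warnings.warn("single carrier: TMRCA is 0 by definition")
        q = {"tmrca": {"median": 0.0, "q025": 0.0, "q975": 0.0, "ess": 1.0}}
        return PosteriorSummary(q, {}, 0), pd.DataFrame()
    return run_mcmc(sub, priors, topology=None, n_iter=n_iter,
                    burn_in=burn_in, thin=thin, seed=seed, **kwargs)


def tree_log_likelihood(table: HaplotypeTable, times, parent, mu,
                        window_margin: int = 12) -> float:
    """Log likelihood of a fixed genealogy under the SMM (pruning over a
    truncated repeat window with a uniform root prior)."""
    priors = PriorSpec(
        mu=Prior("fixed", max(mu, 1e-6)), n0=Prior("fixed", 1000.0),
        growth=Prior("fixed", 0.0), beta=Prior("fixed", 0.0),
    )
    chain = StrMCMC(table, priors, topology=None, seed=0,
                    window_margin=window_margin)
    chain.times = np.asarray(times, dtype=float)
    chain.parent = np.asarray(parent, dtype=np.int64)
    chain.mu = float(mu)
    chain._rebuild_children()
    chain._refresh_postorder()
    return float(chain._full_likelihood_main())


def coalescent_log_prior(table: HaplotypeTable, times, parent,
                         n0_total: float, growth_rate: float = 0.0,
                         growth_onset: float = 0.0,
                         topology: str | None = None,
                         split_times: dict | None = None,
                         split_props=None) -> float:
    """Log density of a genealogy under the splitting piecewise-growth
    coalescent (no likelihood term)."""
    priors = PriorSpec(
        mu=Prior("fixed", 1e-3), n0=Prior("fixed", n0_total),
        growth=Prior("fixed", growth_rate),
        beta=Prior("fixed", growth_onset),
    )
    chain = StrMCMC(table, priors, topology=topology, seed=0)
    if split_times:
        for node in chain.split_nodes:
            clade = chain._ptree.clades[node]
            chain.pop_lower[node] = float(split_times[clade])
    if split_props is not None:
        chain.split_props = np.asarray(split_props, dtype=float)
        chain._update_weights()
    chain.times = np.asarray(times, dtype=float)
    chain.parent = np.asarray(parent, dtype=np.int64)
    chain._rebuild_children()
    chain._refresh_postorder()
    _engine.update_node_lca(chain.postorder, chain.left, chain.right,
                            chain.n_tips, chain.tip_branch, chain.pop_parent,
                            chain.pop_depth, chain.node_lca)
    return float(chain._coal_logprior(chain.times))
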