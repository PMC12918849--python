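"""Multispecies-coalescent gene-tree simulation on species trees and networks.

Branch lengths of the species tree are interpreted directly as coalescent
units (2N generations); within a species-tree branch carrying ``k`` gene
lineages, coalescent waiting times are exponential with rate k(k-1)/2
(the censored coalescent), uncoalesced lineages are passed rootward, and
coalescence continues above the root until a single lineage remains.

A species network is a base tree plus reticulation edges. Each reticulation
attaches at a time point on a recipient edge and points to a donor edge
spanning the same time; every gene lineage present on the recipient edge at
that time independently follows the minor (donor) parent with inheritance
probability gamma.

The gamma estimator inverts this simulator: it matches observed gene-tree
topology frequencies against simulation-estimated frequencies on a gamma
grid (fixed simulation seed per grid point) and reports the L2-nearest grid
value, with a nonparametric bootstrap CI over the observed trees.
"""

from __future__ import annotations

import math
import random
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .trees import Node, PhyloTree

__all__ = [
    "SimConfig",
    "Reticulation",
    "ReticNetwork",
    "simulate_gene_trees",
    "simulate_on_network",
    "topology_frequencies",
    "estimate_gamma",
    "GammaGridEstimator",
]

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class SimConfig:
    """Replicate count, sampling design, and seed for MSC simulation."""

    n_replicates: int = 5000
    samples_per_species: int = 1
    #: terminal branches of quartet-based species trees carry no meaningful
    #: length; with one sample per species they are irrelevant to topology,
    #: so by default they are left as given. Set to a float to override all
    #: terminal lengths with a constant.
    terminal_length: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.samples_per_species < 1:
            raise ValueError("samples_per_species must be >= 1")


@dataclass(frozen=True)
class Reticulation:
    """A gene-flow edge: recipient and donor edges named by their tip clades.

    ``recipient_clade`` / ``donor_clade`` identify tree edges as the edge
    above the MRCA of the given tip set. ``time`` is the age (tips = 0) at
    which lineages on the recipient edge may jump to the donor edge, with
    probability ``gamma`` each, independently.
    """

    recipient_clade: FrozenSet[str]
    donor_clade: FrozenSet[str]
    time: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma}")


@dataclass
class ReticNetwork:
    """Species tree (coalescent units) plus reticulation edges."""

    base_tree: PhyloTree
    reticulations: List[Reticulation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ages = _node_ages(self.base_tree)
        sets = self.base_tree.tip_sets()
        by_clade = {sets[n]: n for n in self.base_tree.preorder()}
        for r in self.reticulations:
            for which, clade in (("recipient", r.recipient_clade), ("donor", r.donor_clade)):
                node = by_clade.get(frozenset(clade))
                if node is None:
                    raise ValueError(f"{which} clade {sorted(clade)} is not an edge of the base tree")
                lo = ages[node]
                hi = ages[node.parent] if node.parent is not None else math.inf
                if not (lo <= r.time <= hi):
                    raise ValueError(
                        f"reticulation time {r.time} outside {which} edge span [{lo}, {hi}]"
                    )

    def with_gamma(self, gamma: float) -> "ReticNetwork":
        retics = [
            Reticulation(r.recipient_clade, r.donor_clade, r.time, gamma)
            for r in self.reticulations
        ]
        return ReticNetwork(self.base_tree, retics)


def _node_ages(tree: PhyloTree) -> Dict[Node, float]:
    """Ages (time before present) assuming an ultrametric tree."""
    depths = tree.depths()
    h = max(depths[t] for t in tree.leaves())
    return {n: h - depths[n] for n in tree.preorder()}


class _Lineage:
    __slots__ = ("node",)

    def __init__(self, node: Node) -> None:
        self.node = node


def _check_species_tree(tree: PhyloTree) -> None:
    if not tree.is_ultrametric(ULTRAMETRIC_RTOL):
        raise ValueError("species tree must be ultrametric (coalescent-unit time tree)")
    for n in tree.preorder():
        if n is not tree.root and (n.length is None or n.length <= 0):
            raise ValueError("species-tree branch lengths must be positive")


def _simulate_once(
    tree: PhyloTree,
    ages: Dict[Node, float],
    retics_by_edge: Dict[Node, List[Reticulation]],
    node_by_clade: Dict[FrozenSet[str], Node],
    samples_per_species: int,
    rng: random.Random,
) -> PhyloTree:
    """One censored-coalescent replicate; returns a rooted gene tree."""
    # Event timeline: (age, priority, kind, payload). Reticulations at equal
    # age to a speciation apply before the merge (priority 0 < 1).
    events: List[Tuple[float, int, str, object]] = []
    for n in tree.internal_nodes():
        events.append((ages[n], 1, "speciation", n))
    for edge_child, rlist in retics_by_edge.items():
        for r in rlist:
            events.append((r.time, 0, "retic", (edge_child, r)))
    events.sort(key=lambda e: (e[0], e[1]))

    # Gene-lineage pools keyed by the species-tree node under each active edge.
    pools: Dict[Node, List[Tuple[Node, float]]] = {}  # (gene node, its age)
    for leaf in tree.leaves():
        pool = []
        for i in range(samples_per_species):
            lbl = leaf.label if samples_per_species == 1 else f"{leaf.label}_{i+1}"
            pool.append((Node(label=lbl), 0.0))
        pools[leaf] = pool

    def coalesce(pool: List[Tuple[Node, float]], start: float, end: float) -> None:
        t = start
        while len(pool) > 1:
            k = len(pool)
            t += rng.expovariate(k * (k - 1) / 2.0)
            if t > end:
                return
            i = rng.randrange(k)
            j = rng.randrange(k - 1)
            if j >= i:
                j += 1
            (a, a_age), (b, b_age) = pool[i], pool[j]
            parent = Node()
            a.length = t - a_age
            b.length = t - b_age
            parent.add_child(a)
            parent.add_child(b)
            for idx in sorted((i, j), reverse=True):
                pool.pop(idx)
            pool.append((parent, t))

    now = 0.0
    for age, _prio, kind, payload in events:
        if age > now:
            for pool in pools.values():
                coalesce(pool, now, age)
            now = age
        if kind == "retic":
            _edge_child, r = payload
            rec_node = node_by_clade[r.recipient_clade]
            don_node = node_by_clade[r.donor_clade]
            src = pools.get(rec_node, [])
            moved, stay = [], []
            for item in src:
                (moved if rng.random() < r.gamma else stay).append(item)
            pools[rec_node] = stay
            if moved:
                pools.setdefault(don_node, []).extend(moved)
        else:  # speciation: merge child pools into this node's edge pool
            node = payload
            merged: List[Tuple[Node, float]] = []
            for c in node.children:
                merged.extend(pools.pop(c, []))
            merged.extend(pools.pop(node, []))  # lineages moved here by a retic
            pools[node] = merged

    root_pool = pools[tree.root]
    coalesce(root_pool, now, math.inf)
    gene_root, _ = root_pool[0]
    gene_root.length = None
    return PhyloTree(gene_root, rooted=True)


def _prepare(network_or_tree) -> Tuple[PhyloTree, Dict, Dict, Dict]:
    if isinstance(network_or_tree, ReticNetwork):
        tree = network_or_tree.base_tree
        retics = network_or_tree.reticulations
    else:
        tree = network_or_tree
        retics = []
    _check_species_tree(tree)
    ages = _node_ages(tree)
    sets = tree.tip_sets()
    node_by_clade = {sets[n]: n for n in tree.preorder()}
    retics_by_edge: Dict[Node, List[Reticulation]] = {}
    for r in retics:
        rec_node = node_by_clade[r.recipient_clade]
        retics_by_edge.setdefault(rec_node, []).append(r)
    return tree, ages, retics_by_edge, node_by_clade


def simulate_gene_trees(species_tree: PhyloTree, config: SimConfig) -> List[PhyloTree]:
    """Simulate ``config.n_replicates`` gene trees under the MSC on a species tree."""
    tree = species_tree
    if config.terminal_length is not None:
        tree = tree.copy()
        for leaf in tree.leaves():
            leaf.length = config.terminal_length
    tree, ages, retics_by_edge, node_by_clade = _prepare(tree)
    rng = random.Random(config.seed)
    return [
        _simulate_once(tree, ages, retics_by_edge, node_by_clade, config.samples_per_species, rng)
        for _ in range(config.n_replicates)
    ]


def simulate_on_network(network: ReticNetwork, config: SimConfig) -> List[PhyloTree]:
    """Simulate gene trees under the MSC on a species network.

    Each gene lineage present on a reticulation's recipient edge at the
    reticulation time independently follows the donor (minor) parent with
    probability gamma.
    """
    tree, ages, retics_by_edge, node_by_clade = _prepare(network)
    rng = random.Random(config.seed)
    return [
        _simulate_once(tree, ages, retics_by_edge, node_by_clade, config.samples_per_species, rng)
        for _ in range(config.n_replicates)
    ]


def topology_frequencies(trees: Sequence[PhyloTree]) -> Dict[str, float]:
    """Relative frequency of each rooted topology (canonical string keys)."""
    counts = Counter(t.topology_id() for t in trees)
    n = len(trees)
    return {k: v / n for k, v in counts.items()}


@dataclass
class GammaEstimate:
    gamma: float
    ci_low: float
    ci_high: float
    grid: np.ndarray
    distances: np.ndarray


class GammaGridEstimator:
    """Grid inversion of the network simulator for the inheritance probability.

    Simulation-estimated topology frequencies are precomputed once per grid
    point (with a per-point seed derived deterministically from ``seed``),
    so many observed tree sets can be scored cheaply against the same grid.
    """

    def __init__(
        self,
        network: ReticNetwork,
        grid: Optional[Sequence[float]] = None,
        sims_per_point: int = 2000,
        seed: int = 0,
    ) -> None:
        self.network = network
        self.grid = np.asarray(grid if grid is not None else np.linspace(0.01, 0.99, 50))
        self.sims_per_point = sims_per_point
        self.seed = seed
        self._freqs: List[Dict[str, float]] = []
        for i, g in enumerate(self.grid):
            cfg = SimConfig(n_replicates=sims_per_point, seed=seed * 100003 + i)
            sims = simulate_on_network(network.with_gamma(float(g)), cfg)
            self._freqs.append(topology_frequencies(sims))

    def estimate_from_counts(self, counts: Dict[str, int]) -> Tuple[float, np.ndarray]:
        n = sum(counts.values())
        topos = set(counts)
        for f in self._freqs:
            topos |= set(f)
        topos = sorted(topos)
        obs = np.array([counts.get(t, 0) / n for t in topos])
        dists = np.array(
            [np.sum((obs - np.array([f.get(t, 0.0) for t in topos])) ** 2) for f in self._freqs]
        )
        return float(self.grid[int(np.argmin(dists))]), dists

    def estimate(
        self,
        observed: Sequence[PhyloTree],
        n_bootstrap: int = 200,
        seed: int = 0,
    ) -> GammaEstimate:
        if len(observed) == 0:
            raise ValueError("no observed gene trees")
        if len(observed) < 100:
            warnings.warn("fewer than 100 observed gene trees; gamma estimate will be noisy")
        counts = Counter(t.topology_id() for t in observed)
        ghat, dists = self.estimate_from_counts(counts)
        # nonparametric bootstrap over observed trees (multinomial resampling)
        rng = np.random.default_rng(seed)
        topos = list(counts)
        probs = np.array([counts[t] for t in topos], dtype=float)
        probs /= probs.sum()
        n = len(observed)
        boots = []
        for _ in range(n_bootstrap):
            draw = rng.multinomial(n, probs)
            bcounts = {t: int(c) for t, c in zip(topos, draw) if c}
            b, _ = self.estimate_from_counts(bcounts)
            boots.append(b)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return GammaEstimate(ghat, float(lo), float(hi), self.grid, dists)


def estimate_gamma(
    observed: Sequence[PhyloTree],
    network: ReticNetwork,
    grid: Optional[Sequence[float]] = None,
    sims_per_point: int = 2000,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> GammaEstimate:
    """Estimate the inheritance probability gamma from observed gene trees.

    Grid search over gamma in [0.01, 0.99]: at each grid point gene trees
    are simulated on the network (fixed per-point seed) and the L2 distance
    between simulated and observed topology frequencies is minimized. The
    CI is a percentile bootstrap over the observed trees.
    """
    est = GammaGridEstimator(network, grid=grid, sims_per_point=sims_per_point, seed=seed)
    return est.estimate(observed, n_bootstrap=n_bootstrap, seed=seed + 1)
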