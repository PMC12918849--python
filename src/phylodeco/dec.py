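"""Dispersal-extinction-cladogenesis (DEC) range evolution.

Geographic ranges are subsets of a set of discrete areas (habitats,
ecoregions). Anagenetic evolution along branches is a continuous-time
Markov chain on the 2^A range states (including the unobservable null
range): a range r gains area a at rate d*|r| (equal dispersal multipliers)
and loses any one of its areas at rate e (a single-area range transitions
to the null range, i.e. lineage-local extinction). At cladogenesis a range
splits into an ordered daughter pair by sympatric duplication (single-area
ranges), subset sympatry, or vicariance with one single-area daughter;
the +J extension adds founder-event jumps to an unoccupied area with
weight j (j = 0 recovers plain DEC). Event probabilities are the
normalized weights.

Likelihood is Felsenstein pruning over the range state space with branch
transitions by matrix exponential; the root uses a flat prior over
non-null ranges (``root_prior="flat"``; a range-size-weighted alternative
is available). Stochastic mapping samples joint node states from the
conditional likelihoods and branch histories conditional on endpoints
(rejection sampling with a retry budget, falling back to uniformization),
and tallies dispersal events between pairs of areas: an anagenetic gain of
area b by range r credits 1/|r| to every (a in r) -> b cell, as does a
cladogenetic jump.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy import optimize

from .trees import Node, PhyloTree

__all__ = [
    "RangeMatrix",
    "DECParams",
    "DECStateSpace",
    "reduce_areas",
    "build_Q",
    "cladogenesis_events",
    "dec_loglik",
    "fit_dec",
    "stochastic_map",
    "simulate_ranges",
    "EventLog",
]


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class RangeMatrix:
    """Species x areas binary presence matrix."""

    table: pd.DataFrame  # index species, columns area labels, values 0/1

    def __post_init__(self) -> None:
        vals = self.table.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("range matrix entries must be 0/1")
        if self.table.shape[1] < 2:
            raise ValueError("need at least 2 areas")
        empty = self.table.sum(axis=1) == 0
        if empty.any():
            bad = list(self.table.index[empty])
            raise ValueError(f"species with empty ranges: {bad}")

    @property
    def areas(self) -> List[str]:
        return list(self.table.columns)

    @property
    def species(self) -> List[str]:
        return list(self.table.index)

    def range_bits(self, sp: str) -> int:
        row = self.table.loc[sp]
        bits = 0
        for i, a in enumerate(self.table.columns):
            if row[a]:
                bits |= 1 << i
        return bits


@dataclass
class DECParams:
    d: float
    e: float
    j: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0 or self.j < 0:
            raise ValueError("rates must be non-negative")


class DECStateSpace:
    """All 2^A range states as bitmasks; index 0 is the null range."""

    def __init__(self, areas: Sequence[str]) -> None:
        self.areas = list(areas)
        self.n_areas = len(self.areas)
        if self.n_areas < 2:
            raise ValueError("need at least 2 areas")
        self.n_states = 1 << self.n_areas
        # states ordered null, then by (size, bit value)
        self.states = [0] + sorted(range(1, self.n_states),
                                   key=lambda s: (bin(s).count("1"), s))
        self.index = {s: i for i, s in enumerate(self.states)}

    @property
    def n_observable(self) -> int:
        return self.n_states - 1

    def label(self, bits: int) -> str:
        if bits == 0:
            return "∅"
        return "+".join(a for i, a in enumerate(self.areas) if bits >> i & 1)

    def size(self, bits: int) -> int:
        return bin(bits).count("1")


# ---------------------------------------------------------------------------
# area reduction
# ---------------------------------------------------------------------------


def reduce_areas(ranges: RangeMatrix) -> RangeMatrix:
    """Drop autapomorphic areas, iterating to a fixpoint.

    An area is dropped when exactly one species occupies it and that
    species also occupies at least one other retained area (single-species
    areas are unlikely to have been ancestral). An area that is a species'
    only remaining area is never dropped.
    """
    tab = ranges.table.copy()
    changed = True
    while changed:
        changed = False
        for a in list(tab.columns):
            occupants = tab.index[tab[a] == 1]
            if len(occupants) != 1:
                continue
            sp = occupants[0]
            if tab.loc[sp].sum() > 1:
                tab = tab.drop(columns=[a])
                changed = True
                break
    return RangeMatrix(tab)


# ---------------------------------------------------------------------------
# anagenetic rate matrix and cladogenesis
# ---------------------------------------------------------------------------


def build_Q(params: DECParams, space: DECStateSpace) -> np.ndarray:
    """Anagenetic rate matrix over the full state space (null included).

    r -> r+{a}: d * |r|; r -> r-{a}: e (single-area ranges go to the null
    range, which is absorbing). Rows sum to zero.
    """
    n = space.n_states
    Q = np.zeros((n, n))
    for s in space.states:
        if s == 0:
            continue
        i = space.index[s]
        size = space.size(s)
        for a in range(space.n_areas):
            bit = 1 << a
            if s & bit:
                Q[i, space.index[s & ~bit]] += params.e
            else:
                Q[i, space.index[s | bit]] += params.d * size
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def cladogenesis_events(
    parent_bits: int,
    params: DECParams,
    space: DECStateSpace,
) -> Dict[Tuple[int, int], float]:
    """Ordered daughter-range pairs with normalized probabilities.

    Events (weight 1 unless noted): sympatric duplication (r, r) for
    single-area r; subset sympatry (a, r) and (r, a) for a in r when
    |r| > 1; vicariance (a, r-a) and (r-a, a) for a in r when |r| > 1
    (deduplicated when |r| = 2); jump (b, r) and (r, b) for b outside r
    with weight j.
    """
    r = parent_bits
    if r == 0:
        raise ValueError("null parent range cannot speciate")
    size = space.size(r)
    weights: Dict[Tuple[int, int], float] = {}

    def add(pair: Tuple[int, int], w: float) -> None:
        weights[pair] = weights.get(pair, 0.0) + w

    singles = [1 << a for a in range(space.n_areas) if r >> a & 1]
    if size == 1:
        add((r, r), 1.0)
    else:
        for s in singles:
            add((s, r), 1.0)
            add((r, s), 1.0)
            rest = r & ~s
            add((s, rest), 1.0)
            if space.size(rest) > 1:
                add((rest, s), 1.0)
    if params.j > 0:
        for a in range(space.n_areas):
            b = 1 << a
            if not r & b:
                add((b, r), params.j)
                add((r, b), params.j)
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _root_prior(space: DECStateSpace, kind: str) -> np.ndarray:
    """Prior over state indices; the null range always has mass zero."""
    pi = np.zeros(space.n_states)
    if kind == "flat":
        pi[1:] = 1.0 / space.n_observable
    elif kind == "size-weighted":
        for s in space.states[1:]:
            pi[space.index[s]] = 1.0 / space.size(s)
        pi /= pi.sum()
    else:
        raise ValueError("root prior must be 'flat' or 'size-weighted'")
    return pi


def _transition_matrices(
    tree: PhyloTree, Q: np.ndarray
) -> Dict[Node, np.ndarray]:
    """expm(Q t) per branch, cached by branch length."""
    cache: Dict[float, np.ndarray] = {}
    out: Dict[Node, np.ndarray] = {}
    for n in tree.preorder():
        if n.parent is None:
            continue
        t = float(n.length)
        if t not in cache:
            try:
                cache[t] = expm(Q * t)
            except Exception as exc:  # pragma: no cover
                raise RuntimeError(
                    f"matrix exponential failed for branch length {t}; "
                    "consider rescaling branch lengths"
                ) from exc
        out[n] = cache[t]
    return out


class _PruneData:
    """Shared pruning state for likelihood and stochastic mapping."""

    def __init__(
        self,
        tree: PhyloTree,
        ranges: RangeMatrix,
        params: DECParams,
        space: Optional[DECStateSpace] = None,
        root_prior: str = "flat",
    ) -> None:
        self.tree = tree
        self.space = space or DECStateSpace(ranges.areas)
        if set(ranges.species) < set(tree.tip_labels):
            missing = sorted(set(tree.tip_labels) - set(ranges.species))
            raise ValueError(f"tips without range data: {missing}")
        self.params = params
        self.Q = build_Q(params, self.space)
        self.P = _transition_matrices(tree, self.Q)
        self.prior = _root_prior(self.space, root_prior)
        self.clado: Dict[int, Dict[Tuple[int, int], float]] = {}
        for s in self.space.states[1:]:
            self.clado[s] = cladogenesis_events(s, params, self.space)

        # conditional likelihoods
        self.L: Dict[Node, np.ndarray] = {}     # at node, below-and-including node state
        self.Dmsg: Dict[Node, np.ndarray] = {}  # at top of node's branch: P @ L
        idx = self.space.index
        for n in tree.postorder():
            if n.is_leaf:
                v = np.zeros(self.space.n_states)
                v[idx[ranges.range_bits(n.label)]] = 1.0
                self.L[n] = v
            else:
                kids = n.children
                if len(kids) != 2:
                    raise ValueError("DEC likelihood requires a binary tree")
                d1 = self.P[kids[0]] @ self.L[kids[0]]
                d2 = self.P[kids[1]] @ self.L[kids[1]]
                self.Dmsg[kids[0]], self.Dmsg[kids[1]] = d1, d2
                v = np.zeros(self.space.n_states)
                for s, events in self.clado.items():
                    i = idx[s]
                    acc = 0.0
                    for (a, b), w in events.items():
                        acc += w * d1[idx[a]] * d2[idx[b]]
                    v[i] = acc
                self.L[n] = v

    def loglik(self) -> float:
        like = float(self.prior @ self.L[self.tree.root])
        if like <= 0:
            return -np.inf
        return math.log(like)


def dec_loglik(
    tree: PhyloTree,
    ranges: RangeMatrix,
    params: DECParams,
    root_prior: str = "flat",
) -> float:
    """DEC log-likelihood by Felsenstein pruning over the range state space."""
    return _PruneData(tree, ranges, params, root_prior=root_prior).loglik()


@dataclass
class DECFit:
    params: DECParams
    loglik: float
    aic: float
    model: str
    converged: bool


def fit_dec(
    tree: PhyloTree,
    ranges: RangeMatrix,
    model: str = "DEC",
    root_prior: str = "flat",
    n_starts: int = 3,
    seed: int = 0,
) -> DECFit:
    """ML estimation of (d, e[, j]) by bounded multi-start optimization.

    AIC uses k = 2 for DEC and k = 3 for DEC+J. DEC+J nests DEC at j = 0,
    so its optimal likelihood is never lower.
    """
    model = model.upper().replace(" ", "")
    if model not in ("DEC", "DEC+J"):
        raise ValueError("model must be 'DEC' or 'DEC+J'")
    with_j = model == "DEC+J"
    rng = np.random.default_rng(seed)
    k = 3 if with_j else 2

    def unpack(theta: np.ndarray) -> DECParams:
        d, e = math.exp(theta[0]), math.exp(theta[1])
        j = math.exp(theta[2]) if with_j else 0.0
        return DECParams(d, e, j)

    def nll(theta: np.ndarray) -> float:
        try:
            return -dec_loglik(tree, ranges, unpack(theta), root_prior)
        except (ValueError, RuntimeError):
            return np.inf

    h = tree.height()
    base = math.log(1.0 / max(h, 1e-9))
    best = None
    ok = False
    for s in range(n_starts):
        x0 = base + rng.normal(scale=1.0, size=k) - 1.0
        if with_j:
            x0[2] = rng.normal(scale=1.0) - 1.0
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
            ok = ok or res.success
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimization starts failed")
    params = unpack(best.x)
    ll = -float(best.fun)
    return DECFit(params, ll, 2 * k - 2 * ll, model, bool(ok))


# ---------------------------------------------------------------------------
# stochastic mapping
# ---------------------------------------------------------------------------


@dataclass
class EventLog:
    """Recorded dispersal events: (branch tip-set id, time, source bits, gained area index)."""

    events: List[Tuple[str, float, int, int]] = field(default_factory=list)

    def dispersal_counts(self, space: DECStateSpace) -> pd.DataFrame:
        M = np.zeros((space.n_areas, space.n_areas))
        for _, _, src, gained in self.events:
            size = space.size(src)
            if size == 0:
                continue
            for a in range(space.n_areas):
                if src >> a & 1:
                    M[a, gained] += 1.0 / size
        return pd.DataFrame(M, index=space.areas, columns=space.areas)


def _sample_path_rejection(
    Q: np.ndarray, s: int, j: int, t: float, rng: random.Random, max_tries: int
) -> Optional[List[Tuple[float, int, int]]]:
    """Forward-simulate a CTMC path from state s of duration t until it ends at j.

    Returns a list of (time, from_state, to_state) jumps, or None if the
    retry budget is exhausted.
    """
    n = Q.shape[0]
    for _ in range(max_tries):
        path = []
        cur = s
        now = 0.0
        while True:
            rate = -Q[cur, cur]
            if rate <= 0:
                break
            now += rng.expovariate(rate)
            if now >= t:
                break
            probs = Q[cur].copy()
            probs[cur] = 0.0
            probs = np.maximum(probs, 0.0)
            tot = probs.sum()
            u = rng.random() * tot
            acc = 0.0
            nxt = cur
            for m in range(n):
                acc += probs[m]
                if u <= acc:
                    nxt = m
                    break
            path.append((now, cur, nxt))
            cur = nxt
        if cur == j:
            return path
    return None


def _sample_path_uniformization(
    Q: np.ndarray, P_t: np.ndarray, s: int, j: int, t: float, rng: random.Random
) -> List[Tuple[float, int, int]]:
    """Endpoint-conditioned path via uniformization."""
    lam = float(np.max(-np.diag(Q)))
    if lam <= 0:
        return []
    n = Q.shape[0]
    R = np.eye(n) + Q / lam
    # sample number of uniformized jumps N | s, j, t
    p_end = P_t[s, j]
    Rpow = [np.eye(n)]
    probs = []
    total = 0.0
    nmax = 0
    poisson_term = math.exp(-lam * t)
    while total < 0.9999 and nmax < 500:
        pr = poisson_term * Rpow[-1][s, j] / p_end
        probs.append(max(pr, 0.0))
        total += probs[-1]
        Rpow.append(Rpow[-1] @ R)
        nmax += 1
        poisson_term *= lam * t / nmax
    u = rng.random() * min(total, 1.0)
    N = 0
    acc = 0.0
    for i, pr in enumerate(probs):
        acc += pr
        if u <= acc:
            N = i
            break
    else:
        N = len(probs) - 1
    if N == 0:
        return []
    times = sorted(rng.random() * t for _ in range(N))
    path = []
    cur = s
    for i in range(N):
        remaining = N - i - 1
        w = R[cur] * Rpow[remaining][:, j]
        tot = w.sum()
        if tot <= 0:
            nxt = cur
        else:
            u2 = rng.random() * tot
            acc2 = 0.0
            nxt = cur
            for m in range(n):
                acc2 += w[m]
                if u2 <= acc2:
                    nxt = m
                    break
        if nxt != cur:
            path.append((times[i], cur, nxt))
        cur = nxt
    return path


@dataclass
class StochasticMapResult:
    dispersal_counts: pd.DataFrame        # mean per-replicate fractional counts
    per_map_counts: List[pd.DataFrame]
    node_states: Dict[str, Dict[int, float]]  # node id -> sampled-state frequencies


def stochastic_map(
    tree: PhyloTree,
    ranges: RangeMatrix,
    params: DECParams,
    n_maps: int = 50,
    seed: int = 0,
    root_prior: str = "flat",
    max_rejection_tries: int = 50,
) -> StochasticMapResult:
    """Sample range histories conditional on tip ranges; tally dispersals.

    Per replicate: the root state is drawn from prior x conditional
    likelihood; cladogenetic events and daughter branch endpoint states are
    sampled from their conditional distributions; branch histories are
    drawn by rejection sampling (capped retries) with a uniformization
    fallback. An anagenetic gain of area b by range r credits 1/|r| to each
    (a in r) -> b dispersal cell; a cladogenetic jump does the same.
    """
    data = _PruneData(tree, ranges, params, root_prior=root_prior)
    space, idx = data.space, data.space.index
    states = data.space.states
    rng = random.Random(seed)
    np_rng = np.random.default_rng(seed + 1)

    node_ids: Dict[Node, str] = {}
    c = 0
    for n in tree.preorder():
        node_ids[n] = n.label if n.is_leaf else f"node{c}"
        c += not n.is_leaf

    per_map = []
    node_state_freq: Dict[str, Dict[int, float]] = {node_ids[n]: {} for n in tree.preorder()}

    for _ in range(n_maps):
        M = np.zeros((space.n_areas, space.n_areas))
        # sample root state
        w = data.prior * data.L[tree.root]
        w = w / w.sum()
        root_state = states[int(np_rng.choice(len(w), p=w))]
        assignment: Dict[Node, int] = {tree.root: root_state}
        stack = [tree.root]
        while stack:
            v = stack.pop()
            sv = assignment[v]
            fq = node_state_freq[node_ids[v]]
            fq[sv] = fq.get(sv, 0.0) + 1.0 / n_maps
            if v.is_leaf:
                continue
            c1, c2 = v.children
            d1, d2 = data.Dmsg[c1], data.Dmsg[c2]
            events = data.clado[sv]
            keys = list(events)
            ew = np.array([events[k] * d1[idx[k[0]]] * d2[idx[k[1]]] for k in keys])
            tot = ew.sum()
            if tot <= 0:
                raise RuntimeError("zero-probability cladogenesis during mapping")
            ks = keys[int(np_rng.choice(len(ew), p=ew / tot))]
            s1, s2 = ks
            # tally a jump event
            for start, other in ((s1, s2), (s2, s1)):
                if other == sv and start & ~sv and space.size(start) == 1:
                    gained = int(start).bit_length() - 1
                    size = space.size(sv)
                    for a in range(space.n_areas):
                        if sv >> a & 1:
                            M[a, gained] += 1.0 / size
            for child, start in ((c1, s1), (c2, s2)):
                # endpoint state at the bottom of the branch
                P_t = data.P[child]
                lw = P_t[idx[start]] * data.L[child]
                lw_tot = lw.sum()
                end_idx = int(np_rng.choice(len(lw), p=lw / lw_tot))
                end_state = states[end_idx]
                path = _sample_path_rejection(
                    data.Q, idx[start], end_idx, float(child.length), rng,
                    max_rejection_tries,
                )
                if path is None:
                    path = _sample_path_uniformization(
                        data.Q, P_t, idx[start], end_idx, float(child.length), rng
                    )
                for _t, frm, to in path:
                    sf, st_ = states[frm], states[to]
                    gained_bits = st_ & ~sf
                    if gained_bits and space.size(gained_bits) == 1:
                        gained = gained_bits.bit_length() - 1
                        size = space.size(sf)
                        if size:
                            for a in range(space.n_areas):
                                if sf >> a & 1:
                                    M[a, gained] += 1.0 / size
                assignment[child] = end_state
                stack.append(child)
        per_map.append(pd.DataFrame(M, index=space.areas, columns=space.areas))

    mean = sum(df.to_numpy() for df in per_map) / n_maps
    return StochasticMapResult(
        pd.DataFrame(mean, index=space.areas, columns=space.areas),
        per_map,
        node_state_freq,
    )


# ---------------------------------------------------------------------------
# forward simulation (shared with the synthetic-data generators)
# ---------------------------------------------------------------------------


def simulate_ranges(
    tree: PhyloTree,
    areas: Sequence[str],
    params: DECParams,
    root_range: Optional[Sequence[str]] = None,
    seed: int = 0,
    max_retries: int = 200,
) -> Tuple[RangeMatrix, EventLog]:
    """Forward-simulate a DEC range history root-to-tips.

    Uses the same anagenetic rates and cladogenetic event weights as the
    likelihood. Every dispersal (anagenetic gain or cladogenetic jump) is
    recorded in the EventLog. If any lineage goes extinct (null range at a
    tip), the whole history is resimulated, up to ``max_retries``.
    """
    space = DECStateSpace(areas)
    Q = build_Q(params, space)
    rng = random.Random(seed)
    sets = tree.tip_sets()

    if root_range is not None:
        root_bits = 0
        for a in root_range:
            root_bits |= 1 << space.areas.index(a)
        if root_bits == 0:
            raise ValueError("root range must be non-empty")
    else:
        root_bits = 1 << rng.randrange(space.n_areas)

    clado_cache: Dict[int, List[Tuple[Tuple[int, int], float]]] = {}

    def clado(s: int):
        if s not in clado_cache:
            clado_cache[s] = list(cladogenesis_events(s, params, space).items())
        return clado_cache[s]

    for _attempt in range(max_retries):
        log = EventLog()
        tip_ranges: Dict[str, int] = {}
        extinct = False

        def evolve_branch(s: int, t: float, branch_id: str) -> int:
            now = 0.0
            cur = s
            while cur != 0:
                i = space.index[cur]
                rate = -Q[i, i]
                if rate <= 0:
                    break
                now += rng.expovariate(rate)
                if now >= t:
                    break
                row = Q[i].copy()
                row[i] = 0.0
                tot = row.sum()
                u = rng.random() * tot
                acc = 0.0
                nxt_idx = i
                for m in range(len(row)):
                    acc += row[m]
                    if u <= acc:
                        nxt_idx = m
                        break
                nxt = space.states[nxt_idx]
                gained_bits = nxt & ~cur
                if gained_bits:
                    log.events.append((branch_id, now, cur, gained_bits.bit_length() - 1))
                cur = nxt
            return cur

        def descend(v: Node, s: int) -> None:
            nonlocal extinct
            if extinct:
                return
            if v.is_leaf:
                if s == 0:
                    extinct = True
                else:
                    tip_ranges[v.label] = s
                return
            if s == 0:
                extinct = True
                return
            ev = clado(s)
            u = rng.random()
            acc = 0.0
            pair = ev[-1][0]
            for (p, w) in ev:
                acc += w
                if u <= acc:
                    pair = p
                    break
            (s1, s2) = pair
            for start, other in ((s1, s2), (s2, s1)):
                if other == s and start & ~s and space.size(start) == 1:
                    log.events.append(("clado:" + ",".join(sorted(sets[v])), 0.0, s,
                                       start.bit_length() - 1))
            for child, start in zip(v.children, (s1, s2)):
                branch_id = ",".join(sorted(sets[child]))
                end = evolve_branch(start, float(child.length), branch_id)
                descend(child, end)

        descend(tree.root, root_bits)
        if not extinct:
            rows = {}
            for sp in sorted(tip_ranges):
                rows[sp] = [tip_ranges[sp] >> i & 1 for i in range(space.n_areas)]
            tab = pd.DataFrame.from_dict(rows, orient="index", columns=space.areas)
            return RangeMatrix(tab), log
    raise RuntimeError(
        f"lineage extinction in every one of {max_retries} attempts; lower e"
    )
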