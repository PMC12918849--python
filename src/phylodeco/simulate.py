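"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of a small Andean plant
radiation study: an ultrametric species tree for ~17 species (crown age
~5.6 Myr), quantitative traits with Brownian phylogenetic covariance plus
linear environmental effects, elevations spanning 0-3900 m, geographic
centroids drifting on the tree from a south-central Bolivian origin,
forward-simulated DEC range histories over discrete habitats, and
target-capture loci with planted bootstrap supports and controlled
pairwise divergence.

Every generator is a pure function of (config, seed): the global seed is
expanded into independent per-generator substreams via
``numpy.random.SeedSequence(seed, spawn_key=(stream_index,))``, with a
fixed stream index per generator, so adding a generator never perturbs the
output of the others.

Alongside each simulated dataset the generator returns (and optionally
writes as a JSON sidecar) the ground truth it planted — regression
coefficients, true centroids, dispersal event logs — so downstream
recovery tests never peek at internals.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from . import dec as dec_mod
from .ancestral import OccurrenceSet
from .trees import Node, PhyloTree, parse_newick

__all__ = [
    "ScenarioConfig",
    "TraitSpec",
    "gen_species_tree",
    "gen_species_tree_unconditioned",
    "gen_traits",
    "gen_occurrences",
    "gen_ranges",
    "gen_loci",
    "fixture_deuterocohnia",
    "write_bundle",
]

# fixed substream indices: appending new generators must not renumber these
_STREAMS = {
    "species_tree": 0,
    "traits": 1,
    "occurrences": 2,
    "ranges": 3,
    "loci": 4,
}


def _rng_for(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _pyrng_for(seed: int, stream: str) -> random.Random:
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    return random.Random(int(ss.generate_state(1, dtype=np.uint64)[0] % (2**63)))


@dataclass
class TraitSpec:
    """One quantitative trait: intercept, per-SD environmental slopes, BM rate.

    Slopes apply to z-scored covariates, so units are trait units per
    covariate standard deviation; sigma2 scales the Brownian deviation
    u ~ MVN(0, sigma2 * C-tilde) with C-tilde the unit-height covariance.
    """

    name: str
    beta0: float = 0.0
    beta_elev: float = 0.0
    beta_temp: float = 0.0
    beta_prec: float = 0.0
    sigma2: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")


#: morphology loosely mirroring a terrestrial bromeliad: compact growth and
#: short inflorescences at high elevation (negative elevation slopes)
DEFAULT_TRAITS = [
    TraitSpec("rosette_size", 0.0, -0.5, 0.0, 0.2, 0.5),
    TraitSpec("flower_length", 0.0, 0.0, 0.5, 0.0, 0.5),
    TraitSpec("floral_bract_length", 0.0, 0.0, 0.0, 0.0, 0.5),
    TraitSpec("floral_bract_width", 0.0, 0.0, 0.0, 0.0, 0.5),
    TraitSpec("leaf_length", 0.0, -0.3, 0.4, 0.0, 0.5),
    TraitSpec("leaf_width", 0.0, -0.2, 0.0, 0.0, 0.5),
    TraitSpec("inflorescence_length", 0.0, -0.5, 0.0, 0.0, 0.5),
    TraitSpec("partial_inflorescence_length", 0.0, -0.6, 0.0, 0.0, 0.5),
    TraitSpec("primary_bract_length", 0.0, 0.0, 0.0, 0.0, 0.5),
    TraitSpec("peduncle_length", 0.0, -0.7, 0.0, 0.0, 0.5),
]

DEFAULT_AREAS = ["puna", "prepuna", "yungas", "chaco", "monte", "atacama", "interandean"]


@dataclass
class ScenarioConfig:
    """All knobs for the synthetic study system, with one global seed."""

    n_species: int = 17
    birth_rate: float = 0.4
    death_rate: float = 0.02
    crown_age: float = 5.6               # Myr; tree rescaled to this height
    fixed_tree: Optional[str] = None     # Newick overriding the birth-death draw

    # reticulation (used by callers building networks; gamma in (0,1))
    gamma: float = 0.25

    # traits / covariates
    traits: List[TraitSpec] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    elev_root: float = 2000.0            # m
    elev_bm_rate: float = 2.5e5          # m^2 / Myr
    elev_range: Tuple[float, float] = (0.0, 3900.0)
    temp_sea_level: float = 24.0         # deg C at 0 m
    temp_lapse: float = 5.5e-3           # deg C per m
    temp_noise_sd: float = 1.0
    prec_log_root: float = math.log(500.0)   # mm/yr
    prec_log_bm_rate: float = 0.08

    # occurrences
    records_per_species: int = 30
    occ_dispersion: float = 0.3          # degrees, isotropic
    centroid_root: Tuple[float, float] = (-21.9, -64.8)  # (lat, lon)
    centroid_bm_rate: Tuple[float, float] = (2.0, 1.0)   # deg^2/Myr (lat, lon)

    # DEC ranges
    areas: List[str] = field(default_factory=lambda: list(DEFAULT_AREAS))
    dec_d: float = 0.25                  # dispersals / lineage / Myr (per source area)
    dec_e: float = 0.02
    dec_j: float = 0.0
    root_range: Optional[List[str]] = None

    # loci
    n_loci: int = 500
    locus_taxa: int = 10
    seq_length: int = 1000
    p_strong_locus: float = 0.5          # fraction of loci with mostly strong nodes
    divergence_low: float = 0.0
    divergence_high: float = 0.30

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        for r in (self.birth_rate, self.death_rate, self.elev_bm_rate,
                  self.prec_log_bm_rate, self.dec_d, self.dec_e, self.dec_j):
            if r < 0:
                raise ValueError("rates must be non-negative")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


def gen_species_tree(config: ScenarioConfig) -> PhyloTree:
    """Ultrametric birth-death species tree with ``n_species`` tips.

    Conditioned on the tip count, then rescaled so the crown age equals
    ``config.crown_age``. Tips are relabeled sp01..spNN in Newick order.
    Deterministic under the config seed.
    """
    if config.fixed_tree is not None:
        return parse_newick(config.fixed_tree)
    rng = _pyrng_for(config.seed, "species_tree")
    dt = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=config.death_rate,
        num_extant_tips=config.n_species,
        rng=rng,
    )
    tree = parse_newick(dt.as_string(schema="newick").replace("[&R]", "").strip())
    # the simulation stops exactly at the n-th speciation, leaving zero-length
    # pendant branches; extend every tip by the memoryless waiting time to the
    # next event so terminals are positive (height is rescaled below anyway)
    extra = rng.expovariate(config.n_species * (config.birth_rate + config.death_rate))
    for i, leaf in enumerate(tree.leaves()):
        leaf.label = f"sp{i + 1:02d}"
        leaf.length = (leaf.length or 0.0) + extra
    h = tree.height()
    if h <= 0:
        raise RuntimeError("degenerate birth-death tree of zero height")
    scale = config.crown_age / h
    for n in tree.preorder():
        if n.length is not None:
            n.length *= scale
    return tree


def gen_species_tree_unconditioned(config: ScenarioConfig, max_time: float, rep: int = 0) -> int:
    """One unconditioned birth-death run; returns the number of extant tips.

    Starts from a single lineage, so E[N(t)] = exp((birth - death) * t).
    Total extinction yields 0.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STREAMS["species_tree"], rep))
    rng = random.Random(int(ss.generate_state(1, dtype=np.uint64)[0] % (2**63)))
    # simple Gillespie on the lineage count: the tree itself is not needed
    t, n = 0.0, 1
    lam, mu = config.birth_rate, config.death_rate
    while n > 0:
        rate = n * (lam + mu)
        t += rng.expovariate(rate)
        if t >= max_time:
            break
        n += 1 if rng.random() < lam / (lam + mu) else -1
    return n


# ---------------------------------------------------------------------------
# traits and covariates
# ---------------------------------------------------------------------------


def _bm_on_tree(tree: PhyloTree, rate: float, root_value: float,
                rng: np.random.Generator) -> Dict[str, float]:
    """Simulate Brownian motion along branches; returns tip values."""
    vals: Dict[Node, float] = {tree.root: root_value}
    out: Dict[str, float] = {}
    for n in tree.preorder():
        if n is tree.root:
            continue
        vals[n] = vals[n.parent] + rng.normal(0.0, math.sqrt(rate * n.length))
        if n.is_leaf:
            out[n.label] = vals[n]
    return out


def gen_traits(
    tree: PhyloTree,
    config: ScenarioConfig,
    elevation: Optional[Dict[str, float]] = None,
) -> Tuple[pd.DataFrame, Dict]:
    """Species x (traits + covariates) table with recorded ground truth.

    Elevation evolves by Brownian motion and is clamped to the configured
    range; temperature follows an adiabatic lapse from elevation plus
    noise; precipitation is log-Brownian. Each quantitative trait is
    beta0 + beta.z(covariates) + u with u ~ MVN(0, sigma2 * C-tilde).
    Two ordinal (0/1/2) categorical traits are produced by thresholding
    latent Brownian characters at their empirical terciles.
    """
    rng = _rng_for(config.seed, "traits")
    species = sorted(tree.tip_labels)
    n = len(species)

    if elevation is None:
        raw = _bm_on_tree(tree, config.elev_bm_rate, config.elev_root, rng)
        lo, hi = config.elev_range
        elevation = {s: float(np.clip(raw[s], lo, hi)) for s in species}
    elev = np.array([elevation[s] for s in species])
    temp = config.temp_sea_level - config.temp_lapse * elev + rng.normal(0, config.temp_noise_sd, n)
    lprec = _bm_on_tree(tree, config.prec_log_bm_rate, config.prec_log_root, rng)
    prec = np.exp([lprec[s] for s in species])

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    Ct = tree.vcv().reorder(species).matrix
    Ct = Ct / float(np.max(np.diag(Ct)))
    covz = {"elev": z(elev), "temp": z(temp), "prec": z(prec)}

    table = pd.DataFrame({"elev": elev, "temp": temp, "prec": prec}, index=species)
    truth: Dict = {"traits": {}, "elevation": dict(zip(species, map(float, elev)))}
    for spec in config.traits:
        u = rng.multivariate_normal(np.zeros(n), spec.sigma2 * Ct, method="cholesky") \
            if spec.sigma2 > 0 else np.zeros(n)
        yv = (spec.beta0 + spec.beta_elev * covz["elev"] + spec.beta_temp * covz["temp"]
              + spec.beta_prec * covz["prec"] + u)
        table[spec.name] = yv
        truth["traits"][spec.name] = asdict(spec)

    # ordinal categorical traits from latent Brownian characters
    for cat in ("growth_form", "flower_color"):
        latent = _bm_on_tree(tree, 1.0, 0.0, rng)
        lv = np.array([latent[s] for s in species])
        codes = np.digitize(lv, np.quantile(lv, [1 / 3, 2 / 3]))
        table[cat] = codes.astype(int)
    return table, truth


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------


def gen_occurrences(
    tree: PhyloTree,
    config: ScenarioConfig,
) -> Tuple[OccurrenceSet, pd.DataFrame]:
    """GBIF-like occurrence records around Brownian species centroids.

    True centroids evolve on the tree by independent latitude/longitude
    Brownian motion from the configured root (southern latitudes are
    negative); each species gets ``records_per_species`` isotropic Gaussian
    records around its centroid. Returns the records and the true-centroid
    table (the recovery sidecar).
    """
    if config.occ_dispersion <= 0:
        raise ValueError("occ_dispersion must be positive")
    rng = _rng_for(config.seed, "occurrences")
    species = sorted(tree.tip_labels)
    lat0, lon0 = config.centroid_root
    rlat, rlon = config.centroid_bm_rate
    lat = _bm_on_tree(tree, rlat, lat0, rng)
    lon = _bm_on_tree(tree, rlon, lon0, rng)
    truth = pd.DataFrame({"lat": [lat[s] for s in species],
                          "lon": [lon[s] for s in species]}, index=species)
    rows = []
    for s in species:
        pts_lat = rng.normal(lat[s], config.occ_dispersion, config.records_per_species)
        pts_lon = rng.normal(lon[s], config.occ_dispersion, config.records_per_species)
        for la, lo in zip(pts_lat, pts_lon):
            rows.append((s, float(np.clip(la, -90, 90)), float(np.clip(lo, -180, 180)), False))
    rec = pd.DataFrame(rows, columns=["species", "lat", "lon", "exclude"])
    return OccurrenceSet(rec), truth


# ---------------------------------------------------------------------------
# DEC ranges
# ---------------------------------------------------------------------------


def gen_ranges(
    tree: PhyloTree,
    config: ScenarioConfig,
) -> Tuple[dec_mod.RangeMatrix, dec_mod.EventLog]:
    """Forward-simulated DEC range history (see ``dec.simulate_ranges``).

    Uses the same anagenetic rates and cladogenetic weights as the DEC
    likelihood; the event log records every dispersal for mapping-recovery
    tests. Unset ``root_range`` draws the root uniformly from the non-null
    ranges (matching the likelihood's flat root prior).
    """
    rng = _pyrng_for(config.seed, "ranges")
    root_range = config.root_range
    if root_range is None:
        space = dec_mod.DECStateSpace(config.areas)
        bits = space.states[1:][rng.randrange(space.n_observable)]
        root_range = [a for i, a in enumerate(config.areas) if bits >> i & 1]
    params = dec_mod.DECParams(config.dec_d, config.dec_e, config.dec_j)
    return dec_mod.simulate_ranges(
        tree, config.areas, params, root_range=root_range,
        seed=rng.randrange(2**31),
    )


# ---------------------------------------------------------------------------
# loci
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _random_topology(labels: Sequence[str], rng: random.Random) -> PhyloTree:
    nodes = [Node(label=l, length=1.0) for l in labels]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        j = rng.randrange(len(nodes) - 1)
        if j >= i:
            j += 1
        a, b = nodes[i], nodes[j]
        p = Node(length=1.0)
        p.add_child(a)
        p.add_child(b)
        for k in sorted((i, j), reverse=True):
            nodes.pop(k)
        nodes.append(p)
    nodes[0].length = None
    return PhyloTree(nodes[0])


def gen_loci(config: ScenarioConfig) -> Tuple[List[PhyloTree], List[Tuple[str, str]], Dict]:
    """Gene trees with planted supports plus reference/query sequence pairs.

    Each locus draws its internal-node supports from a two-class mixture:
    'strong' loci draw most supports from [90, 100], 'weak' loci from
    [0, 90). Each locus also gets an ungapped reference sequence and a
    query mutated at exactly round(target * L) sites, so the realized
    p-distance is within 0.5/L of the drawn target (an error is raised if
    the sequence is too short to honor the 0.01 tolerance).
    """
    rng = _pyrng_for(config.seed, "loci")
    L = config.seq_length
    if L < 50:
        raise ValueError("sequence length too short to control p-distance to 0.01")
    labels = [f"g{i+1}" for i in range(config.locus_taxa)]
    trees: List[PhyloTree] = []
    seqs: List[Tuple[str, str]] = []
    truth: Dict = {"loci": []}
    for li in range(config.n_loci):
        t = _random_topology(labels, rng)
        strong = rng.random() < config.p_strong_locus
        supports = []
        for n in t.internal_nodes(exclude_root=True):
            if strong:
                s = rng.uniform(90, 100) if rng.random() < 0.9 else rng.uniform(40, 90)
            else:
                s = rng.uniform(0, 90)
            n.support = round(s, 1)
            supports.append(n.support)
        target = rng.uniform(config.divergence_low, config.divergence_high)
        k = round(target * L)
        if abs(k / L - target) > 0.01:
            raise ValueError(f"cannot realize p-distance {target} at length {L}")
        ref = "".join(rng.choice(_BASES) for _ in range(L))
        pos = rng.sample(range(L), k)
        q = list(ref)
        for p in pos:
            q[p] = rng.choice([b for b in _BASES if b != ref[p]])
        query = "".join(q)
        trees.append(t)
        seqs.append((ref, query))
        truth["loci"].append({
            "locus": f"locus{li+1:04d}",
            "strong_class": strong,
            "supports": supports,
            "target_p_distance": target,
            "realized_p_distance": k / L,
        })
    return trees, seqs, truth


# ---------------------------------------------------------------------------
# the 17-species fixture
# ---------------------------------------------------------------------------

# synthetic stand-in for the real radiation: clade membership and the
# elevational ordering follow the published qualitative description, but
# branch lengths, elevations and all downstream data are simulated
_FIXTURE_ELEV = {
    "meziana": 1200.0, "brevispicata": 1700.0, "seramisiana": 2200.0,   # clade F
    "chrysantha": 300.0, "strobilifera": 3600.0,                        # clade E
    "schreiteri": 2000.0, "digitata": 3000.0,                           # clade D
    "lotteae": 3100.0, "abstrusa": 3200.0, "brevifolia": 3300.0,        # clade C
    "sanctae_crucis": 1700.0, "gableana": 2000.0, "scapigera": 2800.0,  # clade B
    "recurvipetala": 800.0, "longipetala": 1500.0,
    "haumanii": 1800.0, "glandulosa": 2200.0,                           # clade A
}

FIXTURE_CLADES = {
    "A": ("recurvipetala", "longipetala", "haumanii", "glandulosa"),
    "B": ("sanctae_crucis", "gableana", "scapigera"),
    "C": ("lotteae", "abstrusa", "brevifolia"),
    "D": ("schreiteri", "digitata"),
    "E": ("chrysantha", "strobilifera"),
    "F": ("brevispicata", "meziana", "seramisiana"),
}


def _age_newick(spec) -> str:
    """Build Newick from nested (children, age) tuples; tips are (label, 0)."""

    def rec(node, parent_age):
        if isinstance(node, str):
            return f"{node}:{parent_age:g}"
        children, age = node
        inner = ",".join(rec(c, age) for c in children)
        return f"({inner}):{parent_age - age:g}"

    children, age = spec
    inner = ",".join(rec(c, age) for c in children)
    return f"({inner});"


def fixture_tree() -> PhyloTree:
    """The 17-tip fixture tree: clade F sister to all, then E, then D."""
    spec = ((
        (("brevispicata", (("meziana", "seramisiana"), 1.4)), 2.3),
        ((
            (("chrysantha", "strobilifera"), 3.0),
            ((
                (("schreiteri", "digitata"), 1.8),
                ((
                    (("lotteae", (("abstrusa", "brevifolia"), 0.9)), 1.1),
                    ((
                        (("sanctae_crucis", (("gableana", "scapigera"), 0.8)), 1.0),
                        (("recurvipetala", (("longipetala", (("haumanii", "glandulosa"), 1.0)), 1.6)), 2.4),
                    ), 3.2),
                ), 3.8),
            ), 4.3),
        ), 4.9),
    ), 5.6)
    return parse_newick(_age_newick(spec))


def fixture_deuterocohnia(seed: int = 0) -> Dict:
    """Packaged synthetic bundle mirroring the study system's shape.

    17 tips in six clades (F sister to the rest, then E, then D), crown age
    5.6, tip elevations spanning the 0-3900 m gradient, plus traits,
    occurrences and DEC ranges generated on the fixture tree with the
    default scenario. Ground truths ride along under ``truth``.
    """
    tree = fixture_tree()
    config = ScenarioConfig(seed=seed, fixed_tree=tree.to_newick())
    traits, trait_truth = gen_traits(tree, config, elevation=dict(_FIXTURE_ELEV))
    occ, occ_truth = gen_occurrences(tree, config)
    ranges, event_log = gen_ranges(tree, config)
    return {
        "tree": tree,
        "clades": dict(FIXTURE_CLADES),
        "elevation": dict(_FIXTURE_ELEV),
        "traits": traits,
        "occurrences": occ,
        "ranges": ranges,
        "truth": {
            "traits": trait_truth,
            "centroids": occ_truth,
            "event_log": event_log,
        },
    }


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------


def write_bundle(outdir: str, config: Optional[ScenarioConfig] = None) -> None:
    """Write a full synthetic dataset plus ground-truth JSON sidecar."""
    config = config or ScenarioConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tree = gen_species_tree(config)
    (out / "species_tree.nwk").write_text(tree.to_newick() + "\n")
    traits, trait_truth = gen_traits(tree, config)
    traits.to_csv(out / "traits.csv")
    occ, cent_truth = gen_occurrences(tree, config)
    occ.records.to_csv(out / "occurrences.csv", index=False)
    ranges, events = gen_ranges(tree, config)
    ranges.table.to_csv(out / "ranges.csv")
    gtrees, seqs, locus_truth = gen_loci(config)
    with open(out / "locus_trees.nwk", "w") as fh:
        for t in gtrees:
            fh.write(t.to_newick() + "\n")
    with open(out / "locus_refs.fasta", "w") as fh_r, open(out / "locus_queries.fasta", "w") as fh_q:
        for i, (ref, q) in enumerate(seqs):
            fh_r.write(f">locus{i+1:04d}\n{ref}\n")
            fh_q.write(f">locus{i+1:04d}\n{q}\n")
    sidecar = {
        "config_seed": config.seed,
        "traits": trait_truth,
        "true_centroids": cent_truth.to_dict(orient="index"),
        "dispersal_events": [
            {"branch": b, "time": t, "source_bits": s, "gained_area": config.areas[g]}
            for b, t, s, g in events.events
        ],
        "loci": locus_truth["loci"],
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=1))
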