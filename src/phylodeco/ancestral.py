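"""Maximum-likelihood ancestral states of continuous characters under Brownian motion.

Covers the continuous-character overlays (elevation, PC scores) and the
centroid-biogeography analysis: per-species geographic centroids are the
arithmetic means of occurrence latitudes/longitudes (southern latitudes
negative, western longitudes negative), and ancestral centroids are
obtained by reconstructing latitude and longitude independently as two
univariate Brownian characters. No spherical correction is applied — over
the continental scale of a single radiation the lat/lon plane is treated
as locally Euclidean, which avoids periodicity issues entirely.

The ML state at an internal node equals the GLS phylogenetic mean of the
tip data under the tree re-rooted at that node; the root estimate is
(1' C^-1 1)^-1 1' C^-1 x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .trees import Node, PhyloTree

__all__ = [
    "OccurrenceSet",
    "AncestralStates",
    "centroid",
    "all_centroids",
    "bm_ancestral",
    "ancestral_centroids",
]


@dataclass
class OccurrenceSet:
    """Occurrence records: species, decimal latitude/longitude, exclusion flag.

    Misidentified or otherwise unusable records are handled by the
    ``exclude`` column rather than hard-coded rules.
    """

    records: pd.DataFrame  # columns: species, lat, lon, optional exclude

    def __post_init__(self) -> None:
        req = {"species", "lat", "lon"}
        if not req <= set(self.records.columns):
            raise ValueError(f"occurrence table needs columns {sorted(req)}")
        if "exclude" not in self.records.columns:
            self.records = self.records.assign(exclude=False)
        lat, lon = self.records["lat"], self.records["lon"]
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValueError("longitude outside [-180, 180]")

    def active(self) -> pd.DataFrame:
        return self.records[~self.records["exclude"].astype(bool)]


def centroid(
    occurrences: OccurrenceSet,
    species: str,
    deduplicate: bool = False,
) -> Tuple[float, float]:
    """Geographic centroid (mean latitude, mean longitude) of a species' records.

    ``deduplicate=True`` collapses exactly repeated coordinates before
    averaging (off by default).
    """
    sub = occurrences.active()
    sub = sub[sub["species"] == species]
    if len(sub) == 0:
        raise ValueError(f"no unexcluded records for species {species!r}")
    if deduplicate:
        sub = sub.drop_duplicates(subset=["lat", "lon"])
    return float(sub["lat"].mean()), float(sub["lon"].mean())


def all_centroids(occurrences: OccurrenceSet, deduplicate: bool = False) -> pd.DataFrame:
    """Centroid table (index species, columns lat/lon) for every species present."""
    rows = {}
    for sp in sorted(occurrences.active()["species"].unique()):
        rows[sp] = centroid(occurrences, sp, deduplicate=deduplicate)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["lat", "lon"])


@dataclass
class AncestralStates:
    """Per-node ML estimates and variances; tips carry their observed values."""

    estimates: Dict[str, float]      # node id -> estimate
    variances: Dict[str, float]      # node id -> estimate variance (0 at tips)
    node_tips: Dict[str, Tuple[str, ...]]  # node id -> sorted descendant tips
    root_id: str

    @property
    def root_estimate(self) -> float:
        return self.estimates[self.root_id]


def _node_ids(tree: PhyloTree) -> Dict[Node, str]:
    """Stable node ids: tips by label, internal nodes by a preorder counter."""
    ids: Dict[Node, str] = {}
    counter = 0
    for n in tree.preorder():
        if n.is_leaf:
            ids[n] = n.label
        else:
            ids[n] = f"node{counter}"
            counter += 1
    return ids


def bm_ancestral(tree: PhyloTree, x: Dict[str, float]) -> AncestralStates:
    """Joint ML ancestral states of a continuous character under Brownian motion.

    Each internal node's estimate is the GLS phylogenetic mean of the tips
    under the tree re-rooted at that node, computed from patristic
    distances: with d(v, i) the node-to-tip distance, the re-rooted
    covariance is C_v[i, j] = (d(v,i) + d(v,j) - D[i,j]) / 2. The estimate
    variance is sigma2_hat * (1' C_v^-1 1)^-1 with sigma2_hat the ML rate.
    """
    tips = sorted(tree.tip_labels)
    missing = [t for t in tips if t not in x]
    if missing:
        raise ValueError(f"missing tip values for: {missing}")
    ids = _node_ids(tree)
    sets = tree.tip_sets()
    depths = tree.depths()
    leaf_by_label = {n.label: n for n in tree.leaves()}

    xv = np.array([float(x[t]) for t in tips])
    n = len(tips)
    taxa, D = tree.distance_matrix()
    assert taxa == tips
    tip_index = {t: i for i, t in enumerate(tips)}

    # node-to-tip distances via depths: d(v, i) = depth(i) + depth(v) - 2*depth(mrca)
    # computed directly by traversal instead: distance from v to each tip
    def node_tip_dist(v: Node) -> np.ndarray:
        # distance down into v's subtree, and up over the rest
        dist = np.empty(n)
        below = sets[v]
        for t in tips:
            i = tip_index[t]
            if t in below:
                dist[i] = depths[leaf_by_label[t]] - depths[v]
            else:
                # up to mrca(v, t): depth(v) + depth(t) - 2*depth(mrca)
                # mrca is the deepest ancestor of v containing t
                a = v
                while t not in sets[a]:
                    a = a.parent
                dist[i] = (depths[v] - depths[a]) + (depths[leaf_by_label[t]] - depths[a])
        return dist

    estimates: Dict[str, float] = {}
    variances: Dict[str, float] = {}
    node_tips: Dict[str, Tuple[str, ...]] = {}
    one = np.ones(n)

    # ML rate from the original rooting (rate is rooting-invariant under BM)
    Croot = tree.vcv().matrix  # sorted taxa order == tips
    Ci = np.linalg.inv(Croot)
    mu = float(one @ Ci @ xv) / float(one @ Ci @ one)
    r = xv - mu
    sigma2 = float(r @ Ci @ r) / n

    for v in tree.preorder():
        nid = ids[v]
        node_tips[nid] = tuple(sorted(sets[v]))
        if v.is_leaf:
            estimates[nid] = float(x[v.label])
            variances[nid] = 0.0
            continue
        dv = node_tip_dist(v)
        Cv = 0.5 * (dv[:, None] + dv[None, :] - D)
        np.fill_diagonal(Cv, dv)
        try:
            Cvi = np.linalg.inv(Cv)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular re-rooted covariance (zero-length pendant branch?); "
                "jitter zero-length branches"
            ) from exc
        denom = float(one @ Cvi @ one)
        estimates[nid] = float(one @ Cvi @ xv) / denom
        variances[nid] = sigma2 / denom
    return AncestralStates(estimates, variances, node_tips, ids[tree.root])


def ancestral_centroids(
    tree: PhyloTree,
    centroids: pd.DataFrame,
) -> Tuple[AncestralStates, AncestralStates]:
    """BM ancestral reconstruction of latitude and longitude, independently.

    ``centroids`` is indexed by species with columns ``lat`` and ``lon``.
    The root (lat, lon) pair is the inferred area of origin.
    """
    lat = centroids["lat"].to_dict()
    lon = centroids["lon"].to_dict()
    return bm_ancestral(tree, lat), bm_ancestral(tree, lon)
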