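"""Concordance statistics and ILS attribution.

Three related summaries of a gene-tree set against a reference tree:

* ``clade_support`` — for each rooted clade of the reference, the fraction
  of gene trees (after pruning to shared taxa) in which the clade appears.
  With gene trees simulated under the MSC on a species tree, this is the
  null expectation under incomplete lineage sorting alone: a clade of an
  organellar (e.g. plastome) tree that the null rarely produces points to
  processes beyond ILS such as hybridization or plastome capture.
* ``gene_concordance_factor`` — per internal branch of the reference, the
  percentage of decisive gene trees containing the branch's bipartition.
* ``embedding_fraction`` — the fraction of gene trees in which members of
  one group (e.g. a sister genus) fall inside the smallest clade spanning
  another group, a direct tally of intergeneric admixture signal.

Attribution follows a strict threshold: clades whose null-simulation
frequency exceeds the threshold (default 0.9) are labeled ILS-consistent;
anything at or below it is labeled conflict-beyond-ILS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .trees import PhyloTree

__all__ = [
    "AttributionConfig",
    "CladeSupport",
    "AttributionReport",
    "clade_support",
    "attribute_discordance",
    "gene_concordance_factor",
    "embedding_fraction",
]

ILS_CONSISTENT = "ILS-consistent"
CONFLICT = "conflict-beyond-ILS"


@dataclass
class AttributionConfig:
    """Support threshold and missing-taxon policy for discordance attribution."""

    threshold: float = 0.9
    #: 'prune' scores each clade only in gene trees containing all its taxa
    #: plus at least one outside taxon (prune-then-test); 'strict' restricts
    #: the denominator to gene trees with the full reference taxon set.
    missing_taxon_policy: str = "prune"
    #: score rooted clades ('rooted') or unrooted bipartitions ('bipartition')
    mode: str = "rooted"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.missing_taxon_policy not in ("prune", "strict"):
            raise ValueError("missing_taxon_policy must be 'prune' or 'strict'")
        if self.mode not in ("rooted", "bipartition"):
            raise ValueError("mode must be 'rooted' or 'bipartition'")


@dataclass
class CladeSupport:
    clade: FrozenSet[str]
    frequency: Optional[float]
    denominator: int
    label: Optional[str] = None


@dataclass
class AttributionReport:
    entries: List[CladeSupport] = field(default_factory=list)

    def by_clade(self) -> Dict[FrozenSet[str], CladeSupport]:
        return {e.clade: e for e in self.entries}

    def labels(self) -> Dict[FrozenSet[str], Optional[str]]:
        return {e.clade: e.label for e in self.entries}


def _tree_clades(tree: PhyloTree, restrict_to: Optional[FrozenSet[str]]) -> Tuple[FrozenSet[str], set]:
    """Tip set and rooted-clade set of a gene tree, optionally pruned."""
    taxa = frozenset(tree.tip_labels)
    if restrict_to is not None and not taxa <= restrict_to:
        kept = taxa & restrict_to
        if not kept:
            return frozenset(), set()
        tree = tree.prune(kept)
        taxa = kept
    return taxa, set(tree.clades())


def clade_support(
    reference: PhyloTree,
    trees: Sequence[PhyloTree],
    config: Optional[AttributionConfig] = None,
) -> AttributionReport:
    """Frequency of each reference clade across a gene-tree set.

    For a clade S: frequency = (# trees in which S is a clade after pruning
    to taxa present) / (# trees containing all of S plus >= 1 taxon outside
    S). Clades with an empty denominator get frequency None.
    """
    config = config or AttributionConfig()
    if len(trees) == 0:
        raise ValueError("empty gene-tree set")
    ref_taxa = frozenset(reference.tip_labels)
    if config.mode == "rooted":
        targets = reference.clades()
    else:
        targets = reference.bipartitions()

    # Precompute per-tree taxon sets and clade/bipartition sets.
    per_tree: List[Tuple[FrozenSet[str], set]] = []
    for t in trees:
        taxa, clades = _tree_clades(t, ref_taxa)
        if config.mode == "bipartition":
            bips = set()
            if taxa:
                anchor = min(taxa)
                for c in clades:
                    side = taxa - c if anchor in c else c
                    if len(side) >= 2 and len(taxa) - len(side) >= 2:
                        bips.add(side)
            per_tree.append((taxa, bips))
        else:
            per_tree.append((taxa, clades))

    report = AttributionReport()
    for S in targets:
        denom = hits = 0
        for taxa, clades in per_tree:
            if config.missing_taxon_policy == "strict" and taxa != ref_taxa:
                continue
            if not (S <= taxa) or not (taxa - S):
                continue
            denom += 1
            if config.mode == "rooted":
                present = S in clades
            else:
                anchor = min(taxa)
                side = taxa - S if anchor in S else S
                present = side in clades or (taxa - side) in clades
            if present:
                hits += 1
        freq = hits / denom if denom else None
        report.entries.append(CladeSupport(S, freq, denom))
    return report


def attribute_discordance(
    report: AttributionReport,
    config: Optional[AttributionConfig] = None,
) -> AttributionReport:
    """Label each clade ILS-consistent iff its frequency strictly exceeds the threshold."""
    config = config or AttributionConfig()
    for e in report.entries:
        if e.frequency is None:
            e.label = None
        else:
            e.label = ILS_CONSISTENT if e.frequency > config.threshold else CONFLICT
    return report


# ---------------------------------------------------------------------------
# gene concordance factors
# ---------------------------------------------------------------------------


def _branch_quartet_groups(reference: PhyloTree) -> List[Tuple[FrozenSet[str], List[FrozenSet[str]]]]:
    """Internal branches of the (unrooted) reference with their adjacent subtree groups.

    Each branch is returned as (one side of its bipartition, list of the
    tip-set groups hanging off the two branch endpoints). A gene tree is
    decisive for the branch iff at least two groups on each side retain taxa.
    """
    sets = reference.tip_sets()
    all_tips = frozenset(reference.tip_labels)
    root = reference.root
    root_kids = root.children
    out = []
    seen_bips = set()
    for v in reference.internal_nodes(exclude_root=True):
        side_v = sets[v]
        side_u = all_tips - side_v
        if len(side_v) < 2 or len(side_u) < 2:
            continue
        anchor = min(all_tips)
        key = side_u if anchor in side_v else side_v
        if key in seen_bips:
            continue  # root-adjacent duplicate of the same unrooted branch
        seen_bips.add(key)
        groups_v = [sets[c] for c in v.children]
        u = v.parent
        groups_u = [sets[c] for c in u.children if c is not v]
        if u is not root:
            groups_u.append(all_tips - sets[u])
        elif len(root_kids) == 2:
            # unrooted view: the root is suppressed, the sibling subtree's
            # own children become the adjacent groups
            sib = next(c for c in root_kids if c is not v)
            if not sib.is_leaf:
                groups_u = [sets[c] for c in sib.children]
            else:
                groups_u = [sets[sib]]
        out.append((key, (groups_v, groups_u)))
    return out


def gene_concordance_factor(
    reference: PhyloTree,
    gene_trees: Sequence[PhyloTree],
) -> Dict[FrozenSet[str], Optional[float]]:
    """Per-branch gene concordance factor (percent).

    gCF(b) = 100 x (# gene trees containing b's bipartition after pruning to
    shared taxa) / (# decisive gene trees: those retaining at least one
    taxon in at least two adjacent subtree groups on each side of b).
    Branches with no decisive tree map to None.
    """
    ref_taxa = frozenset(reference.tip_labels)
    branches = _branch_quartet_groups(reference)

    per_tree = []
    for t in gene_trees:
        taxa, clades = _tree_clades(t, ref_taxa)
        if not taxa:
            per_tree.append((taxa, set()))
            continue
        anchor = min(taxa)
        bips = set()
        for c in clades:
            side = taxa - c if anchor in c else c
            if len(side) >= 2 and len(taxa) - len(side) >= 2:
                bips.add(side)
        per_tree.append((taxa, bips))

    out: Dict[FrozenSet[str], Optional[float]] = {}
    for key, (groups_v, groups_u) in branches:
        denom = hits = 0
        for taxa, bips in per_tree:
            nv = sum(1 for g in groups_v if g & taxa)
            nu = sum(1 for g in groups_u if g & taxa)
            if nv < 2 or nu < 2:
                continue
            denom += 1
            side = key & taxa
            comp = taxa - side
            if len(side) < 2 or len(comp) < 2:
                # restriction became trivial; present by definition only if
                # it is a split the gene tree cannot contradict -> count as hit
                hits += 1
                continue
            anchor = min(taxa)
            canon = comp if anchor in side else side
            if canon in bips:
                hits += 1
        out[key] = 100.0 * hits / denom if denom else None
    return out


# ---------------------------------------------------------------------------
# genus-embedding scan
# ---------------------------------------------------------------------------


def embedding_fraction(
    gene_trees: Sequence[PhyloTree],
    group_a: Iterable[str],
    group_b: Iterable[str],
    outgroup: Iterable[str],
) -> Tuple[float, float]:
    """Fraction of gene trees embedding group-B tips inside group A.

    Each gene tree is rooted on the first present outgroup taxon; the
    smallest clade containing all present A tips is located. The tree is
    'some-embedded' if that clade contains at least one present B tip and
    'all-embedded' if it contains every present B tip. Fractions are over
    eligible trees (>= 2 A tips, >= 1 B tip, >= 1 outgroup tip). Raises if
    no tree is eligible.
    """
    A, B, O = set(group_a), set(group_b), set(outgroup)
    if A & B or A & O or B & O:
        raise ValueError("groups A, B and outgroup must be disjoint")
    eligible = some = allb = 0
    for t in gene_trees:
        taxa = set(t.tip_labels)
        a = A & taxa
        b = B & taxa
        o = sorted(O & taxa)
        if len(a) < 2 or not b or not o:
            continue
        eligible += 1
        rooted = t.reroot_at_tip(o[0])
        span = rooted.tip_sets()[rooted.mrca(a)]
        inside = b & span
        if inside:
            some += 1
            if inside == b:
                allb += 1
    if eligible == 0:
        raise ValueError("no eligible gene trees for the embedding scan")
    return some / eligible, allb / eligible
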