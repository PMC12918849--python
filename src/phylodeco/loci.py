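"""Target-capture locus triage for bait-kit design.

A candidate locus passes through three screens:

1. its gene tree has branches below a support threshold (default 70)
   collapsed into polytomies;
2. the collapsed tree is classified: *unresolved* if no internal branch
   survives, *informative* if strictly more than ``min_strong_nodes``
   (default 4) surviving internal branches carry support at or above the
   strong threshold (default 90), otherwise *neither*;
3. its assembled sequence is compared to the corresponding reference
   sequence by p-distance (gap/ambiguity columns excluded), flagged
   divergent at or above the divergence threshold (default 0.15,
   inclusive).

Selected loci are the informative-and-divergent intersection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .trees import PhyloTree

__all__ = [
    "LocusFilterConfig",
    "LocusReport",
    "collapse_low_support",
    "classify_locus",
    "p_distance",
    "select_candidates",
]

UNRESOLVED = "unresolved"
INFORMATIVE = "informative"
NEITHER = "neither"

_AMBIGUOUS = set("NRYSWKMBDHVX?")
_GAP = set("-.")


@dataclass
class LocusFilterConfig:
    collapse_threshold: float = 70.0
    strong_threshold: float = 90.0
    #: informative requires strictly more than this many strong nodes
    min_strong_nodes: int = 4
    divergence_threshold: float = 0.15
    #: how to treat unlabeled internal branches during collapse:
    #: 'collapse' (conservative: treated as support 0) or 'keep'
    unlabeled_policy: str = "collapse"

    def __post_init__(self) -> None:
        if not (0 <= self.collapse_threshold <= 100 and 0 <= self.strong_threshold <= 100):
            raise ValueError("support thresholds must lie in [0, 100]")
        if self.collapse_threshold > self.strong_threshold:
            raise ValueError("collapse threshold must not exceed strong threshold")
        if not (0 <= self.divergence_threshold <= 1):
            raise ValueError("divergence threshold must lie in [0, 1]")
        if self.unlabeled_policy not in ("collapse", "keep"):
            raise ValueError("unlabeled_policy must be 'collapse' or 'keep'")


@dataclass
class LocusReport:
    locus: str
    n_internal_post_collapse: int = 0
    n_strong: int = 0
    classification: str = NEITHER
    p_dist: Optional[float] = None
    divergent: bool = False
    selected: bool = False


def collapse_low_support(
    tree: PhyloTree,
    threshold: float = 70.0,
    unlabeled_policy: str = "collapse",
) -> PhyloTree:
    """Contract internal branches with support below ``threshold`` into polytomies.

    Tip branches and the root are untouched. Unlabeled internal branches are
    treated as support 0 (collapsed) under the default policy, or kept under
    ``unlabeled_policy="keep"``.
    """
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for n in list(t.preorder()):
            if n.is_leaf or n is t.root or n.parent is None:
                continue
            sup = n.support
            weak = (sup is None and unlabeled_policy == "collapse") or (
                sup is not None and sup < threshold
            )
            if weak:
                parent = n.parent
                idx = parent.children.index(n)
                parent.children.pop(idx)
                for i, c in enumerate(n.children):
                    c.parent = parent
                    # absorb the contracted branch's length into nothing:
                    # contraction removes the edge, children keep their own
                    parent.children.insert(idx + i, c)
                changed = True
    return t


def classify_locus(tree: PhyloTree, config: Optional[LocusFilterConfig] = None) -> LocusReport:
    """Collapse-then-classify a locus gene tree.

    Strong nodes are counted on the collapsed tree: the screen first
    removes poorly supported structure, then asks whether enough strongly
    supported resolution remains.
    """
    config = config or LocusFilterConfig()
    collapsed = collapse_low_support(tree, config.collapse_threshold, config.unlabeled_policy)
    internal = collapsed.internal_nodes(exclude_root=True)
    n_internal = len(internal)
    n_strong = sum(
        1 for n in internal if n.support is not None and n.support >= config.strong_threshold
    )
    if n_internal == 0:
        cls = UNRESOLVED
    elif n_strong > config.min_strong_nodes:
        cls = INFORMATIVE
    else:
        cls = NEITHER
    rep = LocusReport(locus="", n_internal_post_collapse=n_internal, n_strong=n_strong,
                      classification=cls)
    return rep


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatches among comparable aligned columns.

    Columns containing a gap or ambiguity code in either sequence are
    excluded. Returns NaN when no column is comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length ({len(a)} vs {len(b)})")
    comparable = mismatch = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _GAP or y in _GAP or x in _AMBIGUOUS or y in _AMBIGUOUS:
            continue
        comparable += 1
        if x != y:
            mismatch += 1
    if comparable == 0:
        return math.nan
    return mismatch / comparable


def select_candidates(
    reports: Sequence[LocusReport],
    config: Optional[LocusFilterConfig] = None,
) -> Dict[str, object]:
    """Intersect informative loci with divergent loci; annotate ``selected``.

    Divergence is inclusive at the threshold (a locus exactly at 0.15 counts
    as divergent); informativeness requires strictly more than
    ``min_strong_nodes`` strong nodes (handled upstream in classify_locus).
    """
    config = config or LocusFilterConfig()
    n_unresolved = n_informative = n_divergent = n_selected = 0
    for r in reports:
        r.divergent = (
            r.p_dist is not None
            and not math.isnan(r.p_dist)
            and r.p_dist >= config.divergence_threshold
        )
        r.selected = r.classification == INFORMATIVE and r.divergent
        n_unresolved += r.classification == UNRESOLVED
        n_informative += r.classification == INFORMATIVE
        n_divergent += r.divergent
        n_selected += r.selected
    return {
        "n_loci": len(reports),
        "n_unresolved": n_unresolved,
        "n_informative": n_informative,
        "n_divergent": n_divergent,
        "n_selected": n_selected,
        "selected": [r.locus for r in reports if r.selected],
    }
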