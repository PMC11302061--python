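"""Dual-mode hierarchical taxonomy annotation.

The retained matches of a read are grouped by full lineage into the
leaves of a weighted taxonomy tree; a leaf's weight is the number of
matched reference sequences carrying that lineage, and every internal
node's weight is the sum of its children.  The final annotation is
resolved under one of two strategies:

* **HWL** (highest weighted leaf) — the leaf with the largest weight,
  preserving full (typically species-level) resolution and carrying the
  best-scoring matched reference id; ties go to the leaf with the
  higher best match score, then lexicographic lineage.
* **LCA** (lowest common ancestor) — the deepest node ancestral to all
  leaves, i.e. the longest common rank-prefix of the leaf lineages;
  conservative, maximizing purity.

Because the HWL leaf is one of the leaves the LCA covers, the LCA
lineage is always a rank-prefix of (or equal to) the HWL lineage.

:func:`recommend_strategy` encodes the habitat-level recommendation
table distilled from large-scale survey data: habitats whose abundant
species have highly consistent 16S sequences (human-associated, most
aquatic and animal habitats for the V4 region) profit from HWL, while
habitats with diverse within-species 16S (soil, sand, plant) are served
better by LCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from pmprofiler.io_formats import Lineage, TaxonomyMap
from pmprofiler.read_search import SearchResult

__all__ = [
    "Leaf",
    "TaxonomyTree",
    "ReadAnnotation",
    "build_tree",
    "annotate_hwl",
    "annotate_lca",
    "annotate_read",
    "recommend_strategy",
    "HABITATS",
]


@dataclass
class Leaf:
    lineage: Lineage
    refs: list[tuple[str, int]]  # (ref_id, match score)

    @property
    def weight(self) -> int:
        return len(self.refs)

    @property
    def best_score(self) -> int:
        return max(s for _, s in self.refs)


@dataclass
class TaxonomyTree:
    """Weighted tree over the lineages of one read's matched references."""

    read_id: str
    leaves: dict[str, Leaf] = field(default_factory=dict)

    @property
    def n_matches(self) -> int:
        return sum(leaf.weight for leaf in self.leaves.values())

    def node_weights(self) -> dict[tuple, int]:
        """Weight of every node (keyed by its rank-path), root included.

        Internal weights are sums over children; the root weight equals
        the number of matched reference sequences.
        """
        weights: dict[tuple, int] = {}
        for leaf in self.leaves.values():
            for depth in range(len(leaf.lineage.ranks) + 1):
                path = leaf.lineage.ranks[:depth]
                weights[path] = weights.get(path, 0) + leaf.weight
        return weights

    def __bool__(self) -> bool:
        return bool(self.leaves)


@dataclass
class ReadAnnotation:
    read_id: str
    strategy: str  # "HWL" | "LCA"
    lineage: Lineage
    best_ref_id: Optional[str] = None
    n_matches: int = 0
    score: Optional[int] = None

    @property
    def is_classified(self) -> bool:
        return len(self.lineage) > 0


_EMPTY = Lineage(())


def build_tree(matches: SearchResult, taxonomy: TaxonomyMap) -> TaxonomyTree:
    """Group a read's retained matches by full lineage into tree leaves.

    Raises ``KeyError`` naming the reference id if a matched reference
    is absent from the taxonomy map.
    """
    tree = TaxonomyTree(read_id=matches.read_id)
    for match in matches.matches:
        if match.ref_id not in taxonomy:
            raise KeyError(f"reference id {match.ref_id!r} missing from taxonomy map")
        lineage = taxonomy[match.ref_id]
        key = str(lineage)
        leaf = tree.leaves.get(key)
        if leaf is None:
            tree.leaves[key] = Leaf(lineage, [(match.ref_id, match.score)])
        else:
            leaf.refs.append((match.ref_id, match.score))
    return tree


def annotate_hwl(tree: TaxonomyTree) -> ReadAnnotation:
    """Resolve to the highest-weighted leaf (ties: best score, then lineage)."""
    if not tree:
        return ReadAnnotation(tree.read_id, "HWL", _EMPTY)
    best_key = min(
        tree.leaves,
        key=lambda key: (-tree.leaves[key].weight, -tree.leaves[key].best_score, key),
    )
    leaf = tree.leaves[best_key]
    best_ref_id, best_score = min(leaf.refs, key=lambda rs: (-rs[1], rs[0]))
    return ReadAnnotation(
        tree.read_id,
        "HWL",
        leaf.lineage,
        best_ref_id=best_ref_id,
        n_matches=tree.n_matches,
        score=best_score,
    )


def annotate_lca(tree: TaxonomyTree, min_leaf_weight: int = 1) -> ReadAnnotation:
    """Resolve to the lowest common ancestor of all (qualifying) leaves.

    ``min_leaf_weight`` optionally ignores leaves supported by fewer
    matched references; the default 1 uses all leaves.  An LCA at the
    root yields an empty (unclassified) lineage.
    """
    if not tree:
        return ReadAnnotation(tree.read_id, "LCA", _EMPTY)
    leaves = [leaf for leaf in tree.leaves.values() if leaf.weight >= min_leaf_weight]
    if not leaves:
        leaves = list(tree.leaves.values())
    lca = leaves[0].lineage
    for leaf in leaves[1:]:
        lca = lca.common_prefix(leaf.lineage)
    return ReadAnnotation(tree.read_id, "LCA", lca, n_matches=tree.n_matches)


def annotate_read(
    matches: SearchResult,
    taxonomy: TaxonomyMap,
    mode: str = "both",
    lca_min_leaf_weight: int = 1,
) -> list[ReadAnnotation]:
    """Annotate one read under the requested strategy/strategies."""
    if mode not in {"hwl", "lca", "both"}:
        raise ValueError(f"mode must be hwl, lca or both, got {mode!r}")
    tree = build_tree(matches, taxonomy)
    out = []
    if mode in {"hwl", "both"}:
        out.append(annotate_hwl(tree))
    if mode in {"lca", "both"}:
        out.append(annotate_lca(tree, min_leaf_weight=lca_min_leaf_weight))
    return out


# --------------------------------------------------------------------------
# habitat-based strategy recommendation
# --------------------------------------------------------------------------

#: The 17-habitat vocabulary of the recommendation table.
HABITATS = (
    "human gut",
    "human skin",
    "human nose",
    "human oral",
    "human urogenital",
    "building",
    "food",
    "freshwater",
    "lake",
    "marine",
    "mammal animal",
    "milk",
    "non-mammal animal",
    "river",
    "plant",
    "soil",
    "sand",
)

_LCA_V4 = {"plant", "soil", "sand"}
_LCA_V3V5 = {"building", "freshwater", "plant", "soil", "sand", "river", "marine", "lake"}


def recommend_strategy(habitat: str, region: str = "V4") -> str:
    """Recommended annotation strategy ("HWL" or "LCA") for a habitat.

    ``region`` is the amplified variable region, "V4" or "V3-V5".
    Unknown habitats fall back to HWL (the default strategy) with a
    warning.
    """
    region_norm = region.replace("–", "-").upper()
    if region_norm not in {"V4", "V3-V5"}:
        raise ValueError(f"unknown variable region {region!r} (expected V4 or V3-V5)")
    habitat_norm = habitat.strip().lower()
    if habitat_norm not in HABITATS:
        warnings.warn(
            f"unknown habitat {habitat!r}; falling back to the default strategy HWL",
            stacklevel=2,
        )
        return "HWL"
    lca_set = _LCA_V4 if region_norm == "V4" else _LCA_V3V5
    return "LCA" if habitat_norm in lca_set else "HWL"
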