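"""Phylogenetic identification of subgenomes from bootstrap-labelled gene trees.

Each focal (polyploid) homoeolog is assigned to a diploid progenitor species
by walking from the focal leaf toward the root and taking the first ancestor
whose clade (a) has bootstrap support at or above a threshold and (b)
contains at least one leaf of a non-ignored diploid species. Focal paralogs,
outgroups and explicitly ignored taxa are transparent: they never block the
walk. If the qualifying clade contains exactly one diploid species the
homoeolog is assigned to it; if it contains two or more, the call is
ambiguous and the search stops (climbing further can only add species); if
no ancestor qualifies the result is a no-call.

Missing supports count as below any positive threshold — absent evidence is
not support — and as zero when the threshold itself is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from octoscope.io import GeneTree, LeafRoleMap, node_support


@dataclass(frozen=True)
class PhyDSParams:
    """Parameters of the subgenome search.

    min_bootstrap : smallest acceptable clade support, in [0, 100].
    ignore_species : species whose leaves are transparent to the search
        (beyond the roles that are always transparent).
    outgroup_preference : species to root on, in order of preference.
    """

    min_bootstrap: int = 80
    ignore_species: frozenset[str] = frozenset()
    outgroup_preference: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.min_bootstrap <= 100:
            raise ValueError(f"min_bootstrap must be in [0, 100], got {self.min_bootstrap}")


@dataclass(frozen=True)
class SubgenomeCall:
    """Outcome of the clade search for one focal leaf."""

    tree_id: str
    focal_leaf: str
    status: str  # assigned | ambiguous | no-call
    called_species: str | None = None
    species_set: frozenset[str] = frozenset()
    clade_support: int | None = None
    clade_size: int = 0


def filter_orthogroup_trees(
    trees: Iterable[GeneTree], role_map: LeafRoleMap, min_unique_species: int = 5
) -> list[GeneTree]:
    """Keep trees whose leaves span at least ``min_unique_species`` species."""
    if min_unique_species < 1:
        raise ValueError("min_unique_species must be >= 1")
    kept = []
    for gt in trees:
        species = {role_map.species(leaf) for leaf in gt.leaf_labels()}
        if len(species) >= min_unique_species:
            kept.append(gt)
    return kept


def root_tree(
    gtree: GeneTree, role_map: LeafRoleMap, outgroup_preference: Sequence[str]
) -> GeneTree:
    """Root on the first preferred outgroup species present; else midpoint.

    The tree is rooted on the edge subtending the smallest clade containing
    all leaves of the chosen species. When no preferred species is present
    (or its leaves do not form a proper clade) the tree is midpoint-rooted
    and flagged, so downstream summaries can exclude it.
    """
    tree = gtree.tree.clone(depth=1)
    tree.is_rooted = True
    for sp in outgroup_preference:
        leaves = [lf for lf in tree.leaf_node_iter() if role_map.species(lf.taxon.label) == sp]
        if not leaves:
            continue
        if len(leaves) == 1:
            node = leaves[0]
        else:
            node = tree.mrca(taxa=[lf.taxon for lf in leaves])
        if node is tree.seed_node:
            continue  # not a proper clade under the current rooting
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
        return GeneTree(gtree.tree_id, tree, midpoint_rooted=False)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 1.0  # unit lengths: midpoint of a support-only tree
    tree.reroot_at_midpoint(update_bipartitions=False)
    return GeneTree(gtree.tree_id, tree, midpoint_rooted=True)


def _effective_support(node: dendropy.Node) -> int:
    sup = node_support(node)
    return 0 if sup is None else sup


def phyds_call(
    gtree: GeneTree, focal_leaf: str, role_map: LeafRoleMap, params: PhyDSParams
) -> SubgenomeCall:
    """Assign one focal homoeolog by the smallest sufficiently supported clade."""
    if role_map.role(focal_leaf) != "focal":
        raise ValueError(f"{focal_leaf!r} does not have role 'focal'")
    tree = gtree.tree
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == focal_leaf:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"focal leaf {focal_leaf!r} not found in tree {gtree.tree_id}")

    node = leaf.parent_node
    while node is not None:
        if _effective_support(node) >= params.min_bootstrap:
            species = {
                role_map.species(lf.taxon.label)
                for lf in node.leaf_iter()
                if role_map.role(lf.taxon.label) == "diploid"
                and role_map.species(lf.taxon.label) not in params.ignore_species
            }
            if len(species) == 1:
                return SubgenomeCall(
                    tree_id=gtree.tree_id,
                    focal_leaf=focal_leaf,
                    status="assigned",
                    called_species=next(iter(species)),
                    species_set=frozenset(species),
                    clade_support=node_support(node),
                    clade_size=sum(1 for _ in node.leaf_iter()),
                )
            if len(species) >= 2:
                return SubgenomeCall(
                    tree_id=gtree.tree_id,
                    focal_leaf=focal_leaf,
                    status="ambiguous",
                    species_set=frozenset(species),
                    clade_support=node_support(node),
                    clade_size=sum(1 for _ in node.leaf_iter()),
                )
            # supported clade without informative diploids: transparent
        node = node.parent_node
    return SubgenomeCall(tree_id=gtree.tree_id, focal_leaf=focal_leaf, status="no-call")


CALL_COLUMNS = [
    "tree_id", "focal_leaf", "threshold", "status", "species", "support", "clade_size",
]


def phyds_batch(
    trees: Iterable[GeneTree],
    role_map: LeafRoleMap,
    params: PhyDSParams,
    thresholds: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Run the clade search for every focal leaf at one or more thresholds.

    Returns a tidy frame with one row per (tree, focal leaf, threshold).
    Thresholds must be ascending; when omitted, ``params.min_bootstrap`` is
    the single threshold.
    """
    if thresholds is None:
        thresholds = [params.min_bootstrap]
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for gt in trees:
        focal = [leaf for leaf in gt.leaf_labels() if role_map.role(leaf) == "focal"]
        for leaf in focal:
            for thr in thresholds:
                p = PhyDSParams(
                    min_bootstrap=thr,
                    ignore_species=params.ignore_species,
                    outgroup_preference=params.outgroup_preference,
                )
                call = phyds_call(gt, leaf, role_map, p)
                rows.append(
                    (
                        gt.tree_id, leaf, thr, call.status, call.called_species,
                        call.clade_support, call.clade_size,
                    )
                )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Count assignments per species per threshold."""
    assigned = calls[calls["status"] == "assigned"]
    out = (
        assigned.groupby(["threshold", "species"]).size().rename("n_assigned").reset_index()
    )
    return out
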