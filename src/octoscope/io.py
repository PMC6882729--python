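"""Readers and writers for the formats the analysis consumes.

Newick gene trees are parsed with dendropy (bootstrap supports as internal
node labels, ``preserve_underscores`` so labels round-trip verbatim), role
maps and tables as TSV via pandas, gene models as GFF3 via gffutils, and
repeat intervals as 3-column BED. All coordinates are 0-based half-open
internally; GFF3's 1-based closed convention is converted only at this
boundary.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import gffutils
import pandas as pd

VALID_ROLES = frozenset({"focal", "diploid", "outgroup", "ignore"})


class RoleMapError(ValueError):
    """A leaf label is missing from, or malformed in, the role map."""


class NewickError(ValueError):
    """A tree in the input stream could not be parsed."""


@dataclass(frozen=True)
class LeafRoleMap:
    """Maps each leaf label to its species name and analysis role.

    Roles: ``focal`` (polyploid homoeologs being assigned), ``diploid``
    (informative progenitor relatives), ``outgroup`` (rooting only) and
    ``ignore`` (transparent to the clade search).
    """

    entries: Mapping[str, tuple[str, str]]  # leaf -> (species, role)

    def __post_init__(self) -> None:
        bad = {leaf: sr for leaf, sr in self.entries.items() if sr[1] not in VALID_ROLES}
        if bad:
            raise RoleMapError(f"invalid roles for leaves: {sorted(bad)}")

    def species(self, leaf: str) -> str:
        return self.entries[leaf][0]

    def role(self, leaf: str) -> str:
        return self.entries[leaf][1]

    def __contains__(self, leaf: str) -> bool:
        return leaf in self.entries

    def species_of_role(self, role: str) -> set[str]:
        return {sp for sp, r in self.entries.values() if r == role}


def read_role_map(path: str | Path) -> LeafRoleMap:
    """Read a 3-column TSV (leaf, species, role) into a LeafRoleMap."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"leaf", "species", "role"}
    if not expected.issubset(df.columns):
        raise RoleMapError(f"role map must have columns {sorted(expected)}, got {list(df.columns)}")
    dup = df["leaf"][df["leaf"].duplicated()]
    if len(dup):
        raise RoleMapError(f"duplicate leaf labels in role map: {sorted(set(dup))}")
    return LeafRoleMap({r.leaf: (r.species, r.role) for r in df.itertuples()})


def write_role_map(role_map: LeafRoleMap, path: str | Path) -> None:
    rows = [(leaf, sp, role) for leaf, (sp, role) in role_map.entries.items()]
    pd.DataFrame(rows, columns=["leaf", "species", "role"]).to_csv(path, sep="\t", index=False)


@dataclass
class GeneTree:
    """A gene tree with bootstrap supports stored as internal node labels.

    ``midpoint_rooted`` flags trees whose preferred outgroup was absent and
    that were therefore midpoint-rooted as a fallback.
    """

    tree_id: str
    tree: dendropy.Tree
    midpoint_rooted: bool = False

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


def node_support(node: dendropy.Node) -> int | None:
    """Bootstrap support of an internal node, or None when absent."""
    label = node.label
    if label is None or label == "":
        return None
    try:
        value = float(label)
    except ValueError as exc:
        raise NewickError(f"internal node label {label!r} is not a number") from exc
    if not 0 <= value <= 100:
        raise NewickError(f"support {value} outside [0, 100]")
    return int(round(value))


def _parse_one(text: str, index: int) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick in tree #{index}: {exc}") from exc


def read_gene_trees(source: str | Path | _io.TextIOBase, role_map: LeafRoleMap) -> list[GeneTree]:
    """Parse a stream of Newick trees and validate leaves against the role map.

    Each tree gets a stable id ``tree<k>`` by stream position. Internal node
    labels, when present, must be numbers in [0, 100]; absent labels are kept
    absent (never coerced to zero).
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        looks_like_path = "(" not in source and "\n" not in source and len(source) < 4096
        text = Path(source).read_text() if looks_like_path and Path(source).exists() else source
    else:
        text = source.read()

    chunks = [c.strip() for c in text.split(";") if c.strip()]
    trees: list[GeneTree] = []
    for i, chunk in enumerate(chunks):
        tree = _parse_one(chunk + ";", i)
        missing = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon.label not in role_map]
        if missing:
            raise RoleMapError(f"tree #{i}: leaves not in role map: {sorted(missing)}")
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise NewickError(f"tree #{i}: duplicate leaf labels")
        for node in tree.preorder_internal_node_iter():
            node_support(node)  # validates label format eagerly
        trees.append(GeneTree(tree_id=f"tree{i}", tree=tree))
    return trees


def write_gene_trees(trees: Iterable[GeneTree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gt in trees:
            fh.write(
                gt.tree.as_string(
                    schema="newick",
                    suppress_rooting=True,
                    unquoted_underscores=True,
                    suppress_edge_lengths=True,
                ).strip()
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / BED

GENE_COLUMNS = ["gene_id", "seqid", "start", "end", "strand"]


def read_genes_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene features from GFF3 into a frame with 0-based half-open coords."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        rows.append((feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_genes_gff3(genes: pd.DataFrame, path: str | Path, source: str = "octoscope") -> None:
    """Write a gene frame (0-based half-open) as GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples():
            fh.write(
                f"{r.seqid}\t{source}\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\tID={r.gene_id}\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3-column BED file (already 0-based half-open)."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["seqid", "start", "end"],
        usecols=[0, 1, 2], comment="#",
    )


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals[["seqid", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
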