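"""Evolutionary age assignment at gene and region level.

Gene age is the ladder stratum of the supertree root.  Region age is the
stratum of the deepest (most ancient) last common ancestor of the human
reference and any homolog in which the region was called conserved —
paralogs count, which is what lets a region predate its orthologous family
when an ancient paralog still carries the motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .formats_io import AnnotatedGeneTree, GeneTreeNode, TaxonomyLadder

__all__ = ["AgeAssignment", "lca", "assign_gene_age", "assign_region_age"]


@dataclass
class AgeAssignment:
    subject: str  # "gene" | "region"
    stratum: str
    node_id: str
    supporting_ids: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)  # reference-only, single-witness


def lca(tree: AnnotatedGeneTree, node_a: str, node_b: str) -> str:
    """Unique lowest common ancestor of two node ids."""
    a = tree.node(node_a)
    b = tree.node(node_b)
    seen = set()
    while a is not None:
        seen.add(a.id)
        a = a.parent
    while b is not None:
        if b.id in seen:
            return b.id
        b = b.parent
    raise ValueError(f"nodes {node_a!r} and {node_b!r} share no ancestor")


def _depth(tree: AnnotatedGeneTree, node_id: str) -> int:
    return len(tree.ancestors(node_id))


def assign_gene_age(tree: AnnotatedGeneTree, ladder: TaxonomyLadder) -> AgeAssignment:
    """Gene-family age: the ladder stratum of the root's taxonomy label."""
    root = tree.root
    stratum = ladder.stratum_of(root.taxon_label)
    return AgeAssignment(
        subject="gene",
        stratum=stratum,
        node_id=root.id,
        supporting_ids=[leaf.leaf_name for leaf in tree.leaves()],
    )


def assign_region_age(
    tree: AnnotatedGeneTree,
    reference_leaf: str,
    conservation_verdicts: Mapping[str, bool],
    ladder: TaxonomyLadder,
) -> AgeAssignment:
    """Region age from per-homolog conservation verdicts.

    The defining node is the deepest LCA of the reference with any
    region-carrying leaf; its taxonomy label, resolved through the ladder,
    is the region's stratum.  With no carrier beyond the reference the
    region is scored at the youngest stratum and flagged ``reference-only``;
    a stratum supported by a single leaf is flagged ``single-witness``.
    """
    ref = tree.leaf_by_name(reference_leaf)
    missing = [
        leaf.leaf_name
        for leaf in tree.leaves()
        if leaf.leaf_name != ref.leaf_name and leaf.leaf_name not in conservation_verdicts
    ]
    if missing:
        raise KeyError(f"missing conservation verdicts for leaves: {missing}")
    carriers = [
        leaf
        for leaf in tree.leaves()
        if leaf.leaf_name != ref.leaf_name and conservation_verdicts[leaf.leaf_name]
    ]
    if not carriers:
        return AgeAssignment(
            subject="region",
            stratum=ladder.youngest,
            node_id=ref.id,
            supporting_ids=[ref.leaf_name],
            flags=["reference-only"],
        )
    best_node: GeneTreeNode | None = None
    best_key: tuple[int, int] | None = None
    support: dict[str, list[str]] = {}
    for leaf in carriers:
        anc_id = lca(tree, ref.id, leaf.id)
        anc = tree.node(anc_id)
        stratum = ladder.stratum_of(anc.taxon_label)
        support.setdefault(anc_id, []).append(leaf.leaf_name)
        key = (ladder.age_index(stratum), -_depth(tree, anc_id))
        if best_key is None or key > best_key:
            best_key = key
            best_node = anc
    assert best_node is not None
    supporting = support[best_node.id]
    flags = ["single-witness"] if len(supporting) == 1 else []
    return AgeAssignment(
        subject="region",
        stratum=ladder.stratum_of(best_node.taxon_label),
        node_id=best_node.id,
        supporting_ids=sorted(supporting),
        flags=flags,
    )
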