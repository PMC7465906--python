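"""Mechanism and fate of region emergence relative to gene duplications.

Mechanism (how the region was born):

* ``neofunctionalization`` — the emergence node sits directly under a
  duplication node (no intervening speciation) and presence is confined to
  exactly one of the duplication's child clades: the copy acquired the
  region right after duplicating.
* ``de_novo`` — everything else, split into sub-scenarios: the region
  predates a later duplication (present in both paralog clades),
  post-dates an earlier duplication (one clade, but separated from the
  duplication by at least one speciation), or has no duplication context.
* ``singleton`` — the family never duplicated at all.
* ``ambiguous`` — the presence pattern is inconsistent with a single birth
  at the stated emergence node; left for human review rather than resolved.

Fate (what happened afterwards): ``not_duplicated`` when no duplication
follows the emergence on region-carrying lineages, ``spread_all`` when
every paralog leaf descending from post-emergence duplications kept the
region, ``partial_loss`` when some lost it.

Only leaf verdicts drive the classification; ancestral presence is never
imputed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .formats_io import AnnotatedGeneTree, GeneTreeNode

__all__ = [
    "EmergenceResult",
    "classify_mechanism",
    "classify_fate",
    "classify",
    "summarize_cohort",
]

MECHANISMS = ("neofunctionalization", "de_novo", "singleton", "ambiguous")
SUB_SCENARIOS = ("pre_duplication", "post_duplication", "no_duplication_context")
FATES = ("not_duplicated", "spread_all", "partial_loss")


@dataclass
class EmergenceResult:
    mechanism: str
    sub_scenario: Optional[str]  # only for de_novo
    fate: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")
        if self.mechanism == "singleton" and self.fate != "not_duplicated":
            raise ValueError("a singleton cannot have post-emergence duplications")


def _carrier_leaves(tree: AnnotatedGeneTree, presence_map: Mapping[str, bool]) -> list[GeneTreeNode]:
    carriers = []
    for leaf in tree.leaves():
        if leaf.leaf_name not in presence_map:
            raise KeyError(f"presence verdict missing for leaf {leaf.leaf_name!r}")
        if presence_map[leaf.leaf_name]:
            carriers.append(leaf)
    return carriers


def _nearest_duplication_above(
    tree: AnnotatedGeneTree, node_id: str
) -> tuple[Optional[GeneTreeNode], int, Optional[GeneTreeNode]]:
    """Walk rootward from a node; return (duplication node, number of
    intervening speciation nodes, the duplication child on the path)."""
    node = tree.node(node_id)
    speciations = 0
    child = node
    current = node.parent
    while current is not None:
        if current.event == "duplication":
            return current, speciations, child
        speciations += 1
        child = current
        current = current.parent
    return None, speciations, None


def classify_mechanism(
    tree: AnnotatedGeneTree,
    emergence_node: str,
    presence_map: Mapping[str, bool],
) -> tuple[str, Optional[str], dict]:
    """Classify how the region arose.  Returns (mechanism, sub_scenario,
    evidence node ids)."""
    node = tree.node(emergence_node)
    carriers = _carrier_leaves(tree, presence_map)
    evidence: dict = {"emergence_node": node.id}

    if not tree.duplication_nodes():
        return "singleton", None, evidence

    # a single birth at the emergence node requires all carriers below it
    outside = [c for c in carriers if not tree.is_ancestor(node.id, c.id)]
    if outside:
        evidence["carriers_outside_emergence_clade"] = sorted(c.leaf_name for c in outside)
        return "ambiguous", None, evidence

    def clade_has_carrier(n: GeneTreeNode) -> bool:
        return any(presence_map.get(l.leaf_name, False) for l in tree.leaves_under(n.id))

    # born before a duplication: the emergence node is (or contains) a
    # duplication whose child clades both carry the region
    if node.event == "duplication" and all(clade_has_carrier(c) for c in node.children):
        evidence["duplication_node"] = node.id
        return "de_novo", "pre_duplication", evidence

    dup_above, speciations_between, path_child = _nearest_duplication_above(tree, node.id)
    if dup_above is not None:
        evidence["duplication_node"] = dup_above.id
        evidence["intervening_speciations"] = speciations_between
        other_children = [c for c in dup_above.children if c is not path_child]
        confined = not any(clade_has_carrier(c) for c in other_children)
        if confined and speciations_between == 0:
            return "neofunctionalization", None, evidence
        if confined:
            return "de_novo", "post_duplication", evidence
        # presence in the sibling clade contradicts the emergence node
        evidence["carriers_in_sibling_clade"] = True
        return "ambiguous", None, evidence

    # no duplication above; a duplication below with both children carrying
    # means the region predates it
    for dup in tree.duplication_nodes():
        if tree.is_ancestor(node.id, dup.id) and dup.id != node.id:
            if all(clade_has_carrier(c) for c in dup.children):
                evidence["duplication_node"] = dup.id
                return "de_novo", "pre_duplication", evidence
    return "de_novo", "no_duplication_context", evidence


def classify_fate(
    tree: AnnotatedGeneTree,
    emergence_node: str,
    presence_map: Mapping[str, bool],
) -> tuple[str, dict]:
    """Classify the region's fate across duplications after its emergence."""
    node = tree.node(emergence_node)
    _carrier_leaves(tree, presence_map)  # validates the map
    post_dups = []
    stack = list(node.children)
    while stack:
        n = stack.pop()
        if n.event == "duplication" and any(
            presence_map.get(l.leaf_name, False) for l in tree.leaves_under(n.id)
        ):
            post_dups.append(n)
        stack.extend(n.children)
    evidence: dict = {
        "emergence_node": node.id,
        "post_emergence_duplications": sorted(d.id for d in post_dups),
    }
    if not post_dups:
        return "not_duplicated", evidence
    all_kept = True
    for dup in post_dups:
        for leaf in tree.leaves_under(dup.id):
            if not presence_map[leaf.leaf_name]:
                all_kept = False
                evidence.setdefault("losses", []).append(leaf.leaf_name)
    if all_kept:
        return "spread_all", evidence
    evidence["losses"] = sorted(evidence["losses"])
    return "partial_loss", evidence


def classify(
    tree: AnnotatedGeneTree,
    emergence_node: str,
    presence_map: Mapping[str, bool],
) -> EmergenceResult:
    mechanism, sub, ev1 = classify_mechanism(tree, emergence_node, presence_map)
    fate, ev2 = classify_fate(tree, emergence_node, presence_map)
    if mechanism == "singleton":
        fate = "not_duplicated"
    return EmergenceResult(mechanism, sub, fate, {**ev1, **ev2})


def summarize_cohort(results: Iterable[EmergenceResult]) -> dict[str, dict[str, int]]:
    results = list(results)
    if not results:
        raise ValueError("no results to summarize")
    return {
        "mechanism": dict(Counter(r.mechanism for r in results)),
        "fate": dict(Counter(r.fate for r in results)),
    }
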