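"""Mechanism and fate classification against hand-built trees and
brute-force leaf-set checks."""

import numpy as np
import pytest

from regionstrat import classify, classify_fate, classify_mechanism, summarize_cohort
from regionstrat.emergence import EmergenceResult
from regionstrat.formats_io import AnnotatedGeneTree, GeneTreeNode


def leaf(species, pid):
    return GeneTreeNode(id=f"{species}|{pid}", event="leaf", species=species, protein_id=pid)


def node(nid, label, children, event="speciation"):
    return GeneTreeNode(id=nid, event=event, taxon_label=label, children=children)


def presence(tree, carriers):
    return {l.leaf_name: (l.leaf_name in carriers) for l in tree.leaves()}


@pytest.fixture
def neo_tree():
    """Duplication at Eumetazoa; region confined to one child clade
    (the beta-catenin/plakoglobin pattern)."""
    copy_a = node("va", "Vertebrata", [leaf("human", "CTNNB1"), leaf("zebrafish", "ctnnb1")])
    copy_b = node("vb", "Vertebrata", [leaf("human", "OTHER"), leaf("zebrafish", "other")])
    dup = node("dup", "Eumetazoa", [copy_a, copy_b], event="duplication")
    root = node("root", "Opisthokonta", [leaf("yeast", "Y1"), dup])
    return AnnotatedGeneTree(root)


class TestMechanism:
    def test_neofunctionalization_one_child_clade(self, neo_tree):
        p = presence(neo_tree, {"human|CTNNB1", "zebrafish|ctnnb1"})
        mech, sub, ev = classify_mechanism(neo_tree, "va", p)
        assert mech == "neofunctionalization"
        assert sub is None
        assert ev["duplication_node"] == "dup"
        assert ev["intervening_speciations"] == 0

    def test_pre_duplication_all_paralogs_carry(self, neo_tree):
        # ID3-style: every paralog kept the region => born before the duplication
        p = presence(
            neo_tree,
            {"human|CTNNB1", "zebrafish|ctnnb1", "human|OTHER", "zebrafish|other"},
        )
        mech, sub, _ = classify_mechanism(neo_tree, "dup", p)
        assert (mech, sub) == ("de_novo", "pre_duplication")

    def test_pre_duplication_with_emergence_above_later_duplication(self):
        # region born at the vertebrate crown, mammal clade duplicated later
        mam_a = node("ma", "Mammalia", [leaf("human", "P1"), leaf("mouse", "P2")])
        mam_b = node("mb", "Mammalia", [leaf("human", "P1b"), leaf("mouse", "P2b")])
        dup = node("dupm", "Mammalia", [mam_a, mam_b], event="duplication")
        vert = node("crown_V", "Vertebrata", [leaf("zebrafish", "P3"), dup])
        root = node("root", "Opisthokonta", [leaf("yeast", "P4"), vert])
        tree = AnnotatedGeneTree(root)
        p = presence(tree, {"human|P1", "mouse|P2", "human|P1b", "mouse|P2b", "zebrafish|P3"})
        mech, sub, _ = classify_mechanism(tree, "crown_V", p)
        assert (mech, sub) == ("de_novo", "pre_duplication")

    def test_post_duplication_with_intervening_speciation(self):
        # ESR1-style: eumetazoan duplication, region born later at Vertebrata
        vert = node("crown_V", "Vertebrata", [leaf("human", "P1"), leaf("zebrafish", "P2")])
        eum_a = node("ea", "Eumetazoa", [leaf("fly", "P3"), vert])
        eum_b = node("eb", "Eumetazoa", [leaf("fly", "P3b"), leaf("human", "P1b")])
        dup = node("dup", "Eumetazoa", [eum_a, eum_b], event="duplication")
        root = node("root", "Opisthokonta", [leaf("yeast", "P4"), dup])
        tree = AnnotatedGeneTree(root)
        p = presence(tree, {"human|P1", "zebrafish|P2"})
        mech, sub, ev = classify_mechanism(tree, "crown_V", p)
        assert (mech, sub) == ("de_novo", "post_duplication")
        assert ev["intervening_speciations"] >= 1

    def test_singleton_without_duplications(self):
        vert = node("crown_V", "Vertebrata", [leaf("human", "P1"), leaf("zebrafish", "P2")])
        root = node("root", "Opisthokonta", [leaf("yeast", "P3"), vert])
        tree = AnnotatedGeneTree(root)
        p = presence(tree, {"human|P1", "zebrafish|P2"})
        mech, sub, _ = classify_mechanism(tree, "crown_V", p)
        assert (mech, sub) == ("singleton", None)

    def test_scattered_presence_is_ambiguous(self, neo_tree):
        # carrier outside the stated emergence clade contradicts a single birth
        p = presence(neo_tree, {"human|CTNNB1", "yeast|Y1"})
        mech, _, ev = classify_mechanism(neo_tree, "va", p)
        assert mech == "ambiguous"
        assert "carriers_outside_emergence_clade" in ev

    def test_unknown_emergence_node_is_error(self, neo_tree):
        with pytest.raises(KeyError):
            classify_mechanism(neo_tree, "nope", presence(neo_tree, set()))

    def test_invariant_under_child_reordering(self, neo_tree):
        p = presence(neo_tree, {"human|CTNNB1", "zebrafish|ctnnb1"})
        before = classify_mechanism(neo_tree, "va", p)[:2]
        for n in neo_tree.preorder():
            n.children = list(reversed(n.children))
        after = classify_mechanism(neo_tree, "va", p)[:2]
        assert before == after


class TestFate:
    def test_partial_loss_vhl_style(self):
        # mammal-level duplication, region kept in VHL but lost in VHLL
        vhl = leaf("human", "VHL")
        vhll = leaf("human", "VHLL")
        dup = node("dupm", "Mammalia", [vhl, vhll], event="duplication")
        vert = node("crown_V", "Eumetazoa", [leaf("zebrafish", "vhl"), dup])
        root = node("root", "Opisthokonta", [leaf("yeast", "Y"), vert])
        tree = AnnotatedGeneTree(root)
        p = presence(tree, {"human|VHL", "zebrafish|vhl"})
        fate, ev = classify_fate(tree, "crown_V", p)
        assert fate == "partial_loss"
        assert ev["losses"] == ["human|VHLL"]

    def test_not_duplicated(self):
        vert = node("crown_V", "Vertebrata", [leaf("human", "P1"), leaf("zebrafish", "P2")])
        root = node("root", "Opisthokonta", [leaf("yeast", "P3"), vert])
        tree = AnnotatedGeneTree(root)
        fate, _ = classify_fate(tree, "crown_V", presence(tree, {"human|P1", "zebrafish|P2"}))
        assert fate == "not_duplicated"

    def test_spread_all_across_two_duplications(self):
        d2a = node("d2a", "Mammalia", [leaf("human", "A1"), leaf("human", "A2")],
                   event="duplication")
        d2b = node("d2b", "Mammalia", [leaf("human", "B1"), leaf("human", "B2")],
                   event="duplication")
        d1 = node("d1", "Vertebrata", [d2a, d2b], event="duplication")
        vert = node("crown_V", "Vertebrata", [leaf("zebrafish", "Z"), d1])
        root = node("root", "Opisthokonta", [leaf("yeast", "Y"), vert])
        tree = AnnotatedGeneTree(root)
        carriers = {"human|A1", "human|A2", "human|B1", "human|B2", "zebrafish|Z"}
        fate, _ = classify_fate(tree, "crown_V", presence(tree, carriers))
        assert fate == "spread_all"

    def test_partial_loss_iff_post_emergence_paralogs_split(self):
        # brute-force check over random presence patterns
        d2a = node("d2a", "Mammalia", [leaf("human", "A1"), leaf("human", "A2")],
                   event="duplication")
        d1 = node("d1", "Vertebrata", [d2a, leaf("human", "B1")], event="duplication")
        vert = node("crown_V", "Vertebrata", [leaf("zebrafish", "Z"), d1])
        root = node("root", "Opisthokonta", [leaf("yeast", "Y"), vert])
        tree = AnnotatedGeneTree(root)
        rng = np.random.default_rng(31)
        names = [l.leaf_name for l in tree.leaves()]
        for _ in range(200):
            carriers = {n for n in names if rng.random() < 0.5}
            p = presence(tree, carriers)
            fate, _ = classify_fate(tree, "crown_V", p)
            # oracle: enumerate post-emergence duplications with carriers below
            dup_leafsets = []
            for d in ("d1", "d2a"):
                below = {l.leaf_name for l in tree.leaves_under(d)}
                if below & carriers:
                    dup_leafsets.append(below)
            if not dup_leafsets:
                assert fate == "not_duplicated"
            elif any(ls - carriers for ls in dup_leafsets):
                assert fate == "partial_loss"
            else:
                assert fate == "spread_all"


class TestCohortSummary:
    def test_counts(self):
        results = [
            EmergenceResult("neofunctionalization", None, "not_duplicated"),
            EmergenceResult("de_novo", "pre_duplication", "spread_all"),
            EmergenceResult("de_novo", "post_duplication", "not_duplicated"),
        ]
        s = summarize_cohort(results)
        assert s["mechanism"] == {"neofunctionalization": 1, "de_novo": 2}
        assert sum(s["mechanism"].values()) == len(results)
        assert sum(s["fate"].values()) == len(results)

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError):
            summarize_cohort([])

    def test_singleton_fate_invariant(self):
        with pytest.raises(ValueError):
            EmergenceResult("singleton", None, "spread_all")
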