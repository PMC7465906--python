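"""Synthetic gene families with a known region-emergence ground truth.

The generator builds a species ladder tree (yeast .. human), optionally
duplicates whole clades, plants a short conserved region at a chosen node
under a chosen scenario, and evolves sequences down the tree, so every
downstream stage — alignment, conservation calls, profile scan, region
dating, mechanism/fate classification — can be tested end to end without
any database download.

Model
-----
* Sites evolve i.i.d. per tree edge: a site substitutes with probability
  ``rate`` and the replacement residue is drawn over the other 19 amino
  acids with probability proportional to ``exp(BLOSUM62 score / 2)``, so
  substitutions are biased toward chemically similar residues.
* The region is the conserved island: ``region_substitution_rate`` must
  not exceed ``flank_substitution_rate``.  Indels occur only in flanks, so
  region coordinates on the reference stay exact by construction.
* Lineages that predate the region's birth carry ancestral background
  content at the region columns, evolving at the flank rate — unrelated to
  the planted region, giving profile scans a clean negative class.
* On ``loss_branches`` the region content is re-randomized (degraded) and
  all descendant leaves are non-carriers.

Randomness comes from one ``numpy`` Generator per family, keyed by
``(seed, family_id)``, so families are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .formats_io import (
    AMINO_ACIDS,
    AnnotatedGeneTree,
    GeneTreeNode,
    MutationTable,
    RiskRegion,
    SubstitutionMatrix,
    TaxonomyLadder,
    default_ladder,
    load_substitution_matrix,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "build_species_tree",
    "apply_duplication",
    "simulate_family",
    "simulate_mutation_table",
    "scenario_config",
    "SCENARIOS",
]

SCENARIOS = ("neofunctionalization", "de_novo_pre_dup", "de_novo_post_dup", "singleton")

# species names per stratum, youngest stratum first
_SPECIES_POOL = {
    "Mammalia": ["human", "mouse", "dog", "cow", "rat"],
    "Vertebrata": ["chicken", "zebrafish", "frog"],
    "Eumetazoa": ["fly", "hydra", "worm"],
    "Opisthokonta": ["yeast"],
}

DEFAULT_SPECIES_PER_STRATUM = {
    "Mammalia": 3,
    "Vertebrata": 2,
    "Eumetazoa": 2,
    "Opisthokonta": 1,
}

DEFAULT_HOTSPOT_PROFILE = ((3, 25), (9, 18), (15, 16))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated gene family."""

    scenario: str
    region_birth_node: str
    ladder: TaxonomyLadder = field(default_factory=default_ladder)
    species_per_stratum: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_PER_STRATUM)
    )
    duplication_events: tuple[tuple[str, str], ...] = ()  # (stratum, target node id)
    region_length: int = 20
    flank_length: int = 60
    flank_substitution_rate: float = 0.08  # per site per edge
    region_substitution_rate: float = 0.01
    flank_indel_rate: float = 0.02  # per flank per edge
    loss_branches: tuple[str, ...] = ()
    hotspot_profile: tuple[tuple[int, int], ...] = DEFAULT_HOTSPOT_PROFILE
    background_mutation_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.region_substitution_rate > self.flank_substitution_rate:
            raise ValueError(
                "region_substitution_rate must not exceed flank_substitution_rate "
                "(the region is the conserved island)"
            )
        if self.scenario == "neofunctionalization" and not self.duplication_events:
            raise ValueError("neofunctionalization requires at least one duplication event")
        if self.scenario == "singleton" and self.duplication_events:
            raise ValueError("a singleton family cannot have duplication events")
        for offset, count in self.hotspot_profile:
            if not (0 <= offset < self.region_length):
                raise ValueError(f"hotspot offset {offset} outside region")
            if count < 0:
                raise ValueError("hotspot counts must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    true_gene_stratum: str
    true_region_stratum: str
    true_emergence_node: str
    true_scenario: str
    true_fate: str
    presence: dict[str, bool] = field(default_factory=dict)  # leaf name -> carrier


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


def build_species_tree(
    ladder: TaxonomyLadder, species_per_stratum: dict[str, int]
) -> AnnotatedGeneTree:
    """Ladder ("caterpillar") species tree, oldest stratum at the root.

    The crown node of stratum S has id ``crown_<S>`` and taxonomy label S;
    within-stratum caterpillar nodes are ``<S>_<k>``.
    """
    inner: GeneTreeNode | None = None  # subtree of all younger strata
    for stratum in ladder.strata:  # youngest first
        k = species_per_stratum.get(stratum, 0)
        pool = _SPECIES_POOL.get(stratum, [])
        names = [pool[i] if i < len(pool) else f"{stratum.lower()}{i}" for i in range(k)]
        leaves = [
            GeneTreeNode(id=f"{sp}|LEAF", event="leaf", species=sp, protein_id="LEAF")
            for sp in names
        ]
        if inner is None:
            # youngest stratum: pure caterpillar of its own species
            if len(leaves) < 2:
                raise ValueError(f"youngest stratum {stratum} needs >= 2 species")
            node = leaves[-1]
            for j in range(len(leaves) - 2, 0, -1):
                node = GeneTreeNode(
                    id=f"{stratum}_{j}",
                    event="speciation",
                    taxon_label=stratum,
                    children=[leaves[j], node],
                )
            inner = GeneTreeNode(
                id=f"crown_{stratum}",
                event="speciation",
                taxon_label=stratum,
                children=[leaves[0], node],
            )
        else:
            node = inner
            for j in range(len(leaves) - 1, 0, -1):
                node = GeneTreeNode(
                    id=f"{stratum}_{j}",
                    event="speciation",
                    taxon_label=stratum,
                    children=[leaves[j], node],
                )
            if leaves:
                inner = GeneTreeNode(
                    id=f"crown_{stratum}",
                    event="speciation",
                    taxon_label=stratum,
                    children=[leaves[0], node],
                )
    assert inner is not None
    return AnnotatedGeneTree(inner)


def _copy_subtree(node: GeneTreeNode, suffix: str) -> GeneTreeNode:
    if node.is_leaf:
        return GeneTreeNode(
            id=f"{node.species}|{node.protein_id}{suffix}",
            event="leaf",
            species=node.species,
            protein_id=f"{node.protein_id}{suffix}",
        )
    return GeneTreeNode(
        id=f"{node.id}_{suffix}",
        event=node.event,
        taxon_label=node.taxon_label,
        children=[_copy_subtree(c, suffix) for c in node.children],
    )


def apply_duplication(
    tree: AnnotatedGeneTree, stratum: str, target_node_id: str | None = None
) -> AnnotatedGeneTree:
    """Duplicate the clade rooted at ``target_node_id`` (default: the crown
    of ``stratum``).  The original subtree keeps its node ids; the copy gets
    a ``b`` suffix on node and protein ids.  The new duplication node is
    ``dup_<target>``."""
    target_id = target_node_id or f"crown_{stratum}"
    target = tree.node(target_id)
    copy = _copy_subtree(target, "b")
    dup = GeneTreeNode(
        id=f"dup_{target_id}",
        event="duplication",
        taxon_label=stratum,
        children=[],
    )
    parent = target.parent
    dup.add_child(target)
    dup.add_child(copy)
    if parent is None:
        return AnnotatedGeneTree(dup)
    parent.children = [dup if c is target else c for c in parent.children]
    dup.parent = parent
    return AnnotatedGeneTree(tree.root)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _substitution_kernel(matrix: SubstitutionMatrix) -> np.ndarray:
    """Row-stochastic replacement kernel: P(new | old), old excluded,
    biased toward positive BLOSUM62 scores."""
    n = len(AMINO_ACIDS)
    K = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        w = np.array(
            [math.exp(matrix.score(a, b) / 2.0) if b != a else 0.0 for b in AMINO_ACIDS]
        )
        K[i] = w / w.sum()
    return K


_AA_IDX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _evolve(seq: np.ndarray, rate: float, kernel: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = rng.choice(len(AMINO_ACIDS), p=kernel[out[i]])
    return out


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, len(AMINO_ACIDS), size=length)


def _decode(arr: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in arr)


def _indel(flank: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rng.random() >= rate:
        return flank
    length = 1 + int(rng.geometric(0.5)) - 1
    length = min(max(length, 1), 3)
    if rng.random() < 0.5 and len(flank) > length + 5:
        pos = int(rng.integers(0, len(flank) - length))
        return np.concatenate([flank[:pos], flank[pos + length :]])
    pos = int(rng.integers(0, len(flank) + 1))
    return np.concatenate([flank[:pos], _random_seq(length, rng), flank[pos:]])


def simulate_mutation_table(
    region: RiskRegion,
    hotspot_profile: Sequence[tuple[int, int]],
    background_rate: float,
    seed: int | np.random.Generator,
) -> MutationTable:
    """COSMIC-style missense counts over a region: exact counts at hotspot
    offsets, Poisson background elsewhere."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hotspots = dict()
    for offset, count in hotspot_profile:
        pos = region.start + offset
        if not region.contains(pos):
            raise ValueError(f"hotspot offset {offset} outside region {region.name}")
        hotspots[pos] = count
    missense = {}
    for pos in region.positions():
        if pos in hotspots:
            missense[pos] = hotspots[pos]
        else:
            c = int(rng.poisson(background_rate))
            if c:
                missense[pos] = c
    return MutationTable(protein_id=region.protein_id, missense=missense)


def simulate_family(
    config: SimulationConfig,
    family_id: int = 0,
    matrix: SubstitutionMatrix | None = None,
) -> tuple[AnnotatedGeneTree, dict[str, str], MutationTable, RiskRegion, GroundTruth]:
    """Simulate one gene family.

    Returns (tree, sequences, mutation table, region on the reference
    protein, ground truth).  The reference is the human leaf of the
    un-suffixed (original) copy.
    """
    matrix = matrix or load_substitution_matrix("BLOSUM62")
    rng = np.random.default_rng([config.seed % (2**31), family_id])
    tree = build_species_tree(config.ladder, config.species_per_stratum)
    for stratum, target in config.duplication_events:
        tree = apply_duplication(tree, stratum, target)
    if config.region_birth_node not in tree:
        raise ValueError(f"region_birth_node {config.region_birth_node!r} absent from tree")
    birth = tree.node(config.region_birth_node)

    reference_name = next(
        leaf.leaf_name for leaf in tree.leaves() if leaf.species == "human" and leaf.protein_id == "LEAF"
    )
    if not tree.is_ancestor(birth.id, tree.leaf_by_name(reference_name).id):
        raise ValueError("region_birth_node must be an ancestor of the human reference leaf")

    kernel = _substitution_kernel(matrix)
    canonical_region = _random_seq(config.region_length, rng)
    loss_set = set(config.loss_branches)
    for b in loss_set:
        if b not in tree:
            raise ValueError(f"loss branch {b!r} absent from tree")

    sequences: dict[str, str] = {}
    presence: dict[str, bool] = {}
    left_flank_len: dict[str, int] = {}

    def descend(
        node: GeneTreeNode,
        left: np.ndarray,
        region: np.ndarray,
        right: np.ndarray,
        carries: bool,
    ) -> None:
        if node.id == birth.id and not carries:
            region = canonical_region.copy()
            carries = True
        if node.id in loss_set and carries:
            region = _random_seq(len(region), rng)
            carries = False
        if node.is_leaf:
            sequences[node.leaf_name] = _decode(np.concatenate([left, region, right]))
            presence[node.leaf_name] = carries
            left_flank_len[node.leaf_name] = len(left)
            return
        for child in node.children:
            rr = config.region_substitution_rate if carries else config.flank_substitution_rate
            c_left = _indel(
                _evolve(left, config.flank_substitution_rate, kernel, rng),
                config.flank_indel_rate,
                rng,
            )
            c_region = _evolve(region, rr, kernel, rng)
            c_right = _indel(
                _evolve(right, config.flank_substitution_rate, kernel, rng),
                config.flank_indel_rate,
                rng,
            )
            descend(child, c_left, c_region, c_right, carries)

    root_left = _random_seq(config.flank_length, rng)
    root_region = _random_seq(config.region_length, rng)  # pre-birth ancestral content
    root_right = _random_seq(config.flank_length, rng)
    descend(tree.root, root_left, root_region, root_right, carries=(birth.id == tree.root.id))

    # region coordinates on the reference protein are exact by construction:
    # indels never touch the region and the reference's flank lengths are known
    ref_seq = sequences[reference_name]
    ref_left_len = left_flank_len[reference_name]
    region = RiskRegion(
        protein_id=reference_name,
        start=ref_left_len + 1,
        end=ref_left_len + config.region_length,
        name=f"synthetic_region_f{family_id}",
        disorder_flag=True,
    )
    assert region.end <= len(ref_seq)
    table = simulate_mutation_table(
        region, config.hotspot_profile, config.background_mutation_rate, rng
    )

    truth = GroundTruth(
        true_gene_stratum=config.ladder.stratum_of(tree.root.taxon_label),
        true_region_stratum=config.ladder.stratum_of(birth.taxon_label),
        true_emergence_node=birth.id,
        true_scenario=config.scenario,
        true_fate=_true_fate(tree, birth, presence),
        presence=presence,
    )
    return tree, sequences, table, region, truth


def _true_fate(tree: AnnotatedGeneTree, birth: GeneTreeNode, presence: dict[str, bool]) -> str:
    post_dups = [
        d
        for d in tree.duplication_nodes()
        if tree.is_ancestor(birth.id, d.id)
        and d.id != birth.id
        and any(presence[l.leaf_name] for l in tree.leaves_under(d.id))
    ]
    if not post_dups:
        return "not_duplicated"
    for d in post_dups:
        if not all(presence[l.leaf_name] for l in tree.leaves_under(d.id)):
            return "partial_loss"
    return "spread_all"


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------


def scenario_config(scenario: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Default study conditions for each planted scenario.

    * ``neofunctionalization`` — vertebrate-clade duplication, region born
      on one copy's crown branch right after the duplication.
    * ``de_novo_pre_dup`` — region born at the vertebrate crown, mammal
      clade duplicated later (region spreads to both copies).
    * ``de_novo_post_dup`` — eumetazoan duplication, region born later at
      the vertebrate crown inside one copy.
    * ``singleton`` — no duplication at all, region born at the vertebrate
      crown.

    ``overrides`` are forwarded to SimulationConfig (e.g. loss_branches to
    force a partial-loss fate).
    """
    presets = {
        "neofunctionalization": dict(
            duplication_events=(("Vertebrata", "crown_Vertebrata"),),
            region_birth_node="crown_Vertebrata",
        ),
        "de_novo_pre_dup": dict(
            duplication_events=(("Mammalia", "crown_Mammalia"),),
            region_birth_node="crown_Vertebrata",
        ),
        "de_novo_post_dup": dict(
            duplication_events=(("Eumetazoa", "crown_Eumetazoa"),),
            region_birth_node="crown_Vertebrata",
        ),
        "singleton": dict(
            duplication_events=(),
            region_birth_node="crown_Vertebrata",
        ),
    }
    if scenario not in presets:
        raise ValueError(f"unknown scenario {scenario!r}")
    kwargs = {**presets[scenario], "scenario": scenario, "seed": seed}
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
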