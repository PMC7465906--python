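"""Readers/writers for the pipeline's external formats plus shared domain types.

Everything downstream works in protein space with 1-based inclusive
coordinates (a region "379-385" covers seven residues).  Trees are Newick
with NHX tags: internal nodes must carry ``D=Y|N`` (duplication flag) and
``T=<taxonomy label>``; leaves are named ``<species>|<protein_id>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "TaxonomyLadder",
    "SubstitutionMatrix",
    "MutationTable",
    "RiskRegion",
    "SelectionSite",
    "GeneTreeNode",
    "AnnotatedGeneTree",
    "read_fasta",
    "write_fasta",
    "read_gene_tree",
    "write_gene_tree",
    "read_regions",
    "read_mutation_tables",
    "write_mutation_tables",
    "read_selection_sites",
    "load_paper_fixture",
    "load_substitution_matrix",
    "DEFAULT_STRATA",
    "DEFAULT_LABEL_MAP",
    "default_ladder",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Taxonomy ladder
# ---------------------------------------------------------------------------

DEFAULT_STRATA = ("Mammalia", "Vertebrata", "Eumetazoa", "Opisthokonta")

# Common ENSEMBL-style clade labels mapped onto the four nested age strata.
# Users extend this via TaxonomyLadder(label_map={...}); unknown labels are a
# hard error rather than a guess.
DEFAULT_LABEL_MAP = {
    "Mammalia": "Mammalia",
    "Homo sapiens": "Mammalia",
    "Hominidae": "Mammalia",
    "Primates": "Mammalia",
    "Euarchontoglires": "Mammalia",
    "Eutheria": "Mammalia",
    "Theria": "Mammalia",
    "Vertebrata": "Vertebrata",
    "Amniota": "Vertebrata",
    "Tetrapoda": "Vertebrata",
    "Sarcopterygii": "Vertebrata",
    "Euteleostomi": "Vertebrata",
    "Gnathostomata": "Vertebrata",
    "Chordata": "Vertebrata",
    "Eumetazoa": "Eumetazoa",
    "Metazoa": "Eumetazoa",
    "Bilateria": "Eumetazoa",
    "Deuterostomia": "Eumetazoa",
    "Protostomia": "Eumetazoa",
    "Opisthokonta": "Opisthokonta",
    "Fungi": "Opisthokonta",
    "Ascomycota": "Opisthokonta",
    "Saccharomyces cerevisiae": "Opisthokonta",
}


@dataclass(frozen=True)
class TaxonomyLadder:
    """Ordered nested age strata, youngest first, plus a label resolver.

    ``strata[0]`` is the youngest stratum (Mammalia by default) and the
    stratum index increases with age.  ``label_map`` translates raw node
    taxonomy labels (e.g. "Sarcopterygii") into strata.
    """

    strata: tuple[str, ...] = DEFAULT_STRATA
    label_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        if len(set(self.strata)) != len(self.strata):
            raise ValueError("ladder strata must be unique")
        for label, stratum in self.label_map.items():
            if stratum not in self.strata:
                raise ValueError(
                    f"label_map entry {label!r} -> {stratum!r} does not resolve to a ladder stratum"
                )

    def stratum_of(self, label: str) -> str:
        if label in self.label_map:
            return self.label_map[label]
        if label in self.strata:
            return label
        raise KeyError(f"taxonomy label {label!r} has no stratum mapping; extend label_map")

    def age_index(self, stratum: str) -> int:
        """0 = youngest; increases with age."""
        try:
            return self.strata.index(stratum)
        except ValueError:
            raise KeyError(f"{stratum!r} is not a ladder stratum") from None

    @property
    def youngest(self) -> str:
        return self.strata[0]

    @property
    def oldest(self) -> str:
        return self.strata[-1]


def default_ladder() -> TaxonomyLadder:
    return TaxonomyLadder()


# ---------------------------------------------------------------------------
# Substitution matrix
# ---------------------------------------------------------------------------


class SubstitutionMatrix:
    """Symmetric amino-acid substitution scores (20 standard residues + X)."""

    def __init__(self, name: str, scores: Mapping[tuple[str, str], int]):
        self.name = name
        self._scores = dict(scores)
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                if self._scores[(a, b)] != self._scores[(b, a)]:
                    raise ValueError(f"matrix {name} not symmetric at ({a},{b})")
            if self._scores[(a, a)] <= 0:
                raise ValueError(f"matrix {name} diagonal not positive at {a}")

    def score(self, a: str, b: str) -> int:
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise KeyError(f"no score for residue pair ({a!r}, {b!r})") from None

    def __call__(self, a: str, b: str) -> int:
        return self.score(a, b)

    @property
    def alphabet(self) -> str:
        return AMINO_ACIDS + "X"


def load_substitution_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a named substitution matrix (currently BLOSUM62 and relatives)."""
    try:
        raw = substitution_matrices.load(name)
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix {name!r}") from None
    letters = AMINO_ACIDS + "X"
    scores = {}
    for a in letters:
        for b in letters:
            scores[(a, b)] = int(raw[a, b])
    return SubstitutionMatrix(name, scores)


# ---------------------------------------------------------------------------
# Mutation tables, regions, selection sites
# ---------------------------------------------------------------------------


@dataclass
class MutationTable:
    """Per-position somatic mutation counts for one protein (COSMIC-style)."""

    protein_id: str
    missense: dict[int, int] = field(default_factory=dict)
    inframe_indel: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, cnt in list(self.missense.items()) + list(self.inframe_indel.items()):
            if pos < 1:
                raise ValueError(f"position {pos} not 1-based")
            if cnt < 0:
                raise ValueError(f"negative count at position {pos}")

    def missense_at(self, position: int) -> int:
        return self.missense.get(position, 0)

    def indel_at(self, position: int) -> int:
        return self.inframe_indel.get(position, 0)

    def total_missense(self, start: int | None = None, end: int | None = None) -> int:
        return sum(
            c for p, c in self.missense.items()
            if (start is None or p >= start) and (end is None or p <= end)
        )

    def total_indel(self, start: int | None = None, end: int | None = None) -> int:
        return sum(
            c for p, c in self.inframe_indel.items()
            if (start is None or p >= start) and (end is None or p <= end)
        )


@dataclass(frozen=True)
class RiskRegion:
    """A mutation-hotspot interval of a protein, 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    name: str = ""
    disorder_flag: bool = True
    functional_unit: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region bounds {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class SelectionSite:
    """A site under branch-site positive selection (Selectome-style)."""

    gene: str
    position: int
    posterior: float
    branch: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.posterior <= 1.0):
            raise ValueError(f"posterior {self.posterior} outside [0,1]")
        if self.position < 1:
            raise ValueError("position must be 1-based")


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------


class GeneTreeNode:
    """Node of an event-annotated gene tree."""

    __slots__ = ("id", "event", "taxon_label", "species", "protein_id", "children", "parent")

    def __init__(
        self,
        id: str,
        event: str,
        taxon_label: str | None = None,
        species: str | None = None,
        protein_id: str | None = None,
        children: list["GeneTreeNode"] | None = None,
    ):
        if event not in ("speciation", "duplication", "leaf"):
            raise ValueError(f"invalid event {event!r} on node {id!r}")
        self.id = id
        self.event = event
        self.taxon_label = taxon_label
        self.species = species
        self.protein_id = protein_id
        self.children: list[GeneTreeNode] = children or []
        self.parent: GeneTreeNode | None = None
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return self.event == "leaf"

    @property
    def leaf_name(self) -> str:
        return f"{self.species}|{self.protein_id}"

    def add_child(self, child: "GeneTreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneTreeNode({self.id!r}, {self.event})"


class AnnotatedGeneTree:
    """Rooted gene tree whose internal nodes carry duplication/speciation
    events and taxonomy labels (the structure ENSEMBL Compara supertrees
    provide via NHX)."""

    def __init__(self, root: GeneTreeNode):
        self.root = root
        self._index: dict[str, GeneTreeNode] = {}
        for node in self.preorder():
            if node.id in self._index:
                raise ValueError(f"duplicate node id {node.id!r}")
            self._index[node.id] = node
        for node in self.preorder():
            if not node.is_leaf:
                if node.event not in ("speciation", "duplication"):
                    raise ValueError(f"internal node {node.id!r} lacks an event annotation")
                if not node.taxon_label:
                    raise ValueError(f"internal node {node.id!r} lacks a taxonomy label")

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[GeneTreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[GeneTreeNode]:
        out: list[GeneTreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaves(self) -> list[GeneTreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def node(self, node_id: str) -> GeneTreeNode:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"node {node_id!r} not in tree") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def leaf_by_name(self, name: str) -> GeneTreeNode:
        for leaf in self.leaves():
            if leaf.leaf_name == name or leaf.id == name:
                return leaf
        raise KeyError(f"no leaf named {name!r}")

    def ancestors(self, node_id: str) -> list[GeneTreeNode]:
        """Path from a node up to (and including) the root."""
        node = self.node(node_id)
        path = []
        while node.parent is not None:
            node = node.parent
            path.append(node)
        return path

    def is_ancestor(self, ancestor_id: str, node_id: str) -> bool:
        if ancestor_id == node_id:
            return True
        return any(a.id == ancestor_id for a in self.ancestors(node_id))

    def leaves_under(self, node_id: str) -> list[GeneTreeNode]:
        node = self.node(node_id)
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            stack.extend(n.children)
        return out

    def duplication_nodes(self) -> list[GeneTreeNode]:
        return [n for n in self.preorder() if n.event == "duplication"]


def _convert_dendropy_node(dnode, counter: list[int]) -> GeneTreeNode:
    ann = {a.name: a.value for a in dnode.annotations}
    if dnode.is_leaf():
        name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
        if "|" not in name:
            raise ValueError(f"leaf {name!r} is not of the form '<species>|<protein_id>'")
        species, protein_id = name.split("|", 1)
        return GeneTreeNode(id=name, event="leaf", species=species, protein_id=protein_id)
    if "D" not in ann:
        where = dnode.label or f"internal node #{counter[0]}"
        raise ValueError(f"missing NHX duplication tag D=Y|N on {where}")
    if "T" not in ann:
        where = dnode.label or f"internal node #{counter[0]}"
        raise ValueError(f"missing NHX taxonomy tag T=<label> on {where}")
    dflag = str(ann["D"]).strip()
    if dflag not in ("Y", "N"):
        raise ValueError(f"invalid duplication flag D={dflag!r}")
    event = "duplication" if dflag == "Y" else "speciation"
    node_id = dnode.label or f"n{counter[0]}"
    counter[0] += 1
    children = [_convert_dendropy_node(c, counter) for c in dnode.child_nodes()]
    return GeneTreeNode(id=node_id, event=event, taxon_label=str(ann["T"]), children=children)


def read_gene_tree(path: str | Path) -> AnnotatedGeneTree:
    """Parse a Newick/NHX gene tree with D= and T= annotations.

    The tree must be rooted (bifurcating root); internal nodes missing the
    event or taxonomy tag are a hard error naming the node.
    """
    dtree = dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True
    )
    root = dtree.seed_node
    # collapse the bare wrapper node that "((...)...);" produces
    while len(root.child_nodes()) == 1 and not root.child_nodes()[0].is_leaf():
        root = root.child_nodes()[0]
    nchild = len(root.child_nodes())
    if nchild > 2:
        raise ValueError(f"tree is unrooted (root has {nchild} children); provide a rooted tree")
    if nchild == 0:
        raise ValueError("tree has no internal structure")
    converted = _convert_dendropy_node(root, counter=[0])
    return AnnotatedGeneTree(converted)


def _node_to_newick(node: GeneTreeNode) -> str:
    if node.is_leaf:
        return node.leaf_name
    inner = ",".join(_node_to_newick(c) for c in node.children)
    dflag = "Y" if node.event == "duplication" else "N"
    return f"({inner}){node.id}[&&NHX:D={dflag}:T={node.taxon_label}]"


def write_gene_tree(tree: AnnotatedGeneTree, path: str | Path) -> None:
    Path(path).write_text(_node_to_newick(tree.root) + ";\n")


def gene_tree_to_newick(tree: AnnotatedGeneTree) -> str:
    return _node_to_newick(tree.root) + ";"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into an ordered id -> sequence map.

    Sequences are upper-cased and stop characters ('*') stripped; duplicate
    ids and empty files are hard errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"FASTA file {path} contains no records")
    out: dict[str, str] = {}
    for rec in records:
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().replace("*", "")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = ["protein_id", "position", "missense_count", "inframe_indel_count"]


def read_mutation_tables(path: str | Path) -> dict[str, MutationTable]:
    """Read a mutation-count TSV (one row per protein position) into one
    MutationTable per protein."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing required columns {missing}")
    tables: dict[str, MutationTable] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        if grp["position"].duplicated().any():
            raise ValueError(f"duplicate positions for protein {pid}")
        tables[str(pid)] = MutationTable(
            protein_id=str(pid),
            missense={int(r.position): int(r.missense_count) for r in grp.itertuples()},
            inframe_indel={
                int(r.position): int(r.inframe_indel_count) for r in grp.itertuples()
            },
        )
    return tables


def write_mutation_tables(tables: Mapping[str, MutationTable], path: str | Path) -> None:
    rows = []
    for pid, table in tables.items():
        positions = sorted(set(table.missense) | set(table.inframe_indel))
        for pos in positions:
            rows.append((pid, pos, table.missense_at(pos), table.indel_at(pos)))
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[RiskRegion]:
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"region table missing column {col!r}")
    regions = []
    for r in df.itertuples():
        functional_unit = getattr(r, "functional_unit", None)
        if pd.isna(functional_unit):
            functional_unit = None
        name = getattr(r, "name_", None) or getattr(r, "name", None)
        if not isinstance(name, str) or not name:
            name = f"{r.protein_id}_{r.start}-{r.end}"
        disorder = getattr(r, "disorder_flag", 1)
        regions.append(
            RiskRegion(
                protein_id=str(r.protein_id),
                start=int(r.start),
                end=int(r.end),
                name=str(name),
                disorder_flag=bool(int(disorder)) if not pd.isna(disorder) else True,
                functional_unit=functional_unit,
            )
        )
    return regions


def read_selection_sites(path: str | Path) -> list[SelectionSite]:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "position", "posterior"):
        if col not in df.columns:
            raise ValueError(f"selection table missing column {col!r}")
    return [
        SelectionSite(
            gene=str(r.gene),
            position=int(r.position),
            posterior=float(r.posterior),
            branch=str(getattr(r, "branch", "")),
        )
        for r in df.itertuples()
    ]


def load_paper_fixture() -> tuple[list[RiskRegion], list[SelectionSite]]:
    """Load the packaged study dataset: the 36 disordered cancer risk regions
    of 32 proteins and the 22 positive-selection sites of CALR/CTNNB1/VHL."""
    data = resources.files("regionstrat") / "data"
    with resources.as_file(data / "regions_paper.tsv") as p:
        regions = read_regions(p)
    with resources.as_file(data / "selectome_table1.tsv") as p:
        sites = read_selection_sites(p)
    return regions, sites


def parse_functional_unit_bounds(functional_unit: str | None) -> tuple[int, int] | None:
    """Extract explicit motif bounds from a functional-unit annotation such
    as ``motif:293-327``; returns None when no bounds are encoded."""
    if not functional_unit:
        return None
    m = re.search(r"(\d+)-(\d+)$", functional_unit)
    if not m:
        return None
    return int(m.group(1)), int(m.group(2))
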