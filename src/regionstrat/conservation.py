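"""Mutation-weighted region conservation.

A risk region is called conserved in a homolog when the alignment columns
that are similar to the human reference (non-negative BLOSUM62 score) carry
strictly more than 50% of the region's missense mutations.  Heavily mutated
positions therefore dominate the call, which is the point: they are the
residues cancer needs intact.

Region-level averages (sorted-conservation curves) use a per-position
conservation defined as the fraction of homolog rows similar (or identical)
to the reference at that column, averaged over positions that clear a
minimum mutation count (tiers 1 / 15 / 25).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .formats_io import AMINO_ACIDS, MutationTable, RiskRegion, SubstitutionMatrix
from .msa import GAP, Alignment, RegionProjection, project_region

__all__ = [
    "ConservationCall",
    "RegionConservationSummary",
    "position_similar",
    "call_region_conservation",
    "summarize_region",
    "filter_dataset",
]

MIN_REGION_MISSENSE = 15  # dataset floor: regions with fewer are excluded


@dataclass
class ConservationCall:
    """Per-homolog verdict on one region."""

    homolog_id: str
    conserved: bool
    mutation_weighted_fraction: float
    verdicts: list[str]  # per position: similar | identical | mismatch | gap
    no_weight: bool = False  # region had zero missense mutations

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_weighted_fraction <= 1.0):
            raise ValueError("fraction outside [0,1]")


@dataclass
class RegionConservationSummary:
    region: RiskRegion
    mode: str  # blosum62 | identity
    min_mutations: int
    positions_used: int
    average_conservation: Optional[float]  # None when no position qualifies

    @property
    def is_empty(self) -> bool:
        return self.average_conservation is None


def position_similar(ref_residue: str, homolog_residue: str, matrix: SubstitutionMatrix) -> bool:
    """Non-negative substitution score => similar; gaps and ambiguity codes
    (X etc.) are never similar."""
    if ref_residue == GAP or homolog_residue == GAP:
        return False
    for r in (ref_residue, homolog_residue):
        if r == "X":
            return False
        if r not in AMINO_ACIDS:
            raise ValueError(f"non-amino-acid character {r!r}")
    return matrix.score(ref_residue, homolog_residue) >= 0


def _verdict(ref: str, hom: str, matrix: SubstitutionMatrix) -> str:
    if hom == GAP or ref == GAP:
        return "gap"
    if hom == ref and ref != "X":
        return "identical"
    if position_similar(ref, hom, matrix):
        return "similar"
    return "mismatch"


def call_region_conservation(
    projection: RegionProjection,
    region: RiskRegion,
    mutation_table: MutationTable,
    matrix: SubstitutionMatrix,
) -> ConservationCall:
    """Decide whether the region is conserved in one homolog.

    fraction = missense carried by similar/identical positions over missense
    carried by all region positions; conserved iff fraction > 0.5 (strict).
    A zero-missense region yields fraction 0 and an explicit no-weight flag.
    """
    positions = list(region.positions())
    if len(projection.pairs) != len(positions):
        raise ValueError(
            f"projection of {projection.homolog_id!r} has {len(projection.pairs)} pairs "
            f"for a {len(positions)}-residue region"
        )
    verdicts = [_verdict(ref, hom, matrix) for ref, hom in projection.pairs]
    total = sum(mutation_table.missense_at(p) for p in positions)
    if total == 0:
        return ConservationCall(projection.homolog_id, False, 0.0, verdicts, no_weight=True)
    carried = sum(
        mutation_table.missense_at(p)
        for p, v in zip(positions, verdicts)
        if v in ("similar", "identical")
    )
    fraction = carried / total
    return ConservationCall(projection.homolog_id, fraction > 0.5, fraction, verdicts)


def summarize_region(
    alignment: Alignment,
    region: RiskRegion,
    mutation_table: MutationTable,
    homolog_set: Sequence[str],
    reference_id: str,
    matrix: SubstitutionMatrix,
    mode: str = "blosum62",
    min_mutations: int = 1,
    weight_by_mutations: bool = False,
) -> RegionConservationSummary:
    """Average per-position conservation across a homolog set.

    Per-position conservation is the fraction of homolog rows whose residue
    is similar (mode ``blosum62``) or identical (mode ``identity``) to the
    reference; the average runs over region positions with at least
    ``min_mutations`` missense mutations.  With ``weight_by_mutations`` the
    qualifying positions are weighted by their counts instead of averaged
    evenly.
    """
    if mode not in ("blosum62", "identity"):
        raise ValueError(f"unknown mode {mode!r}")
    if not homolog_set:
        raise ValueError("homolog_set is empty")
    projections = {
        p.homolog_id: p for p in project_region(alignment, reference_id, region)
    }
    missing = [h for h in homolog_set if h not in projections]
    if missing:
        raise KeyError(f"homologs not in alignment: {missing}")
    positions = list(region.positions())
    per_position: list[float] = []
    weights: list[int] = []
    for k, pos in enumerate(positions):
        count = mutation_table.missense_at(pos)
        if count < min_mutations:
            continue
        ok = 0
        for h in homolog_set:
            ref, hom = projections[h].pairs[k]
            v = _verdict(ref, hom, matrix)
            if mode == "identity":
                ok += v == "identical"
            else:
                ok += v in ("identical", "similar")
        per_position.append(ok / len(homolog_set))
        weights.append(count)
    if not per_position:
        return RegionConservationSummary(region, mode, min_mutations, 0, None)
    if weight_by_mutations:
        avg = sum(c * w for c, w in zip(per_position, weights)) / sum(weights)
    else:
        avg = sum(per_position) / len(per_position)
    return RegionConservationSummary(region, mode, min_mutations, len(per_position), avg)


def filter_dataset(
    regions: Iterable[RiskRegion],
    mutation_tables: Mapping[str, MutationTable],
) -> tuple[list[RiskRegion], dict[str, str]]:
    """Apply the dataset filters: drop regions with fewer than 15 missense
    mutations, and regions primarily (strict majority) mutated by in-frame
    indels.  Returns (retained, reasons for the dropped)."""
    retained: list[RiskRegion] = []
    reasons: dict[str, str] = {}
    for region in regions:
        if region.protein_id not in mutation_tables:
            raise KeyError(f"no mutation table for {region.protein_id!r}")
        table = mutation_tables[region.protein_id]
        missense = table.total_missense(region.start, region.end)
        indels = table.total_indel(region.start, region.end)
        if indels > missense:
            reasons[region.name] = f"indel-dominated ({indels} indel vs {missense} missense)"
        elif missense < MIN_REGION_MISSENSE:
            reasons[region.name] = f"only {missense} missense mutations (< {MIN_REGION_MISSENSE})"
        else:
            retained.append(region)
    return retained, reasons
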