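"""Mapping externally computed positive-selection evidence onto regions.

Selection inference itself (branch-site likelihoods, MK tests) happens
upstream; here Selectome-style site tables are filtered by posterior
probability and intersected with risk-region intervals and mutation
hotspots.  Interval membership is 1-based inclusive on both ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .formats_io import MutationTable, RiskRegion, SelectionSite

__all__ = [
    "SitePlacement",
    "OverlapReport",
    "filter_selection_sites",
    "overlap_regions",
    "overlap_cohort",
    "join_mk_flags",
]

DEFAULT_POSTERIOR_MIN = 0.9
DEFAULT_HOTSPOT_MIN = 15  # missense floor reused as the "highly mutated" bar


@dataclass(frozen=True)
class SitePlacement:
    site: SelectionSite
    in_region: bool
    region_name: Optional[str]
    missense_count: int
    on_hotspot: bool


@dataclass
class OverlapReport:
    gene: str
    sites_total: int
    sites_in_region: int
    sites_on_hotspots: int
    placements: list[SitePlacement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.sites_on_hotspots <= self.sites_in_region <= self.sites_total):
            raise ValueError("inconsistent overlap counts")


def filter_selection_sites(
    sites: Iterable[SelectionSite], posterior_min: float = DEFAULT_POSTERIOR_MIN
) -> list[SelectionSite]:
    """Keep sites with posterior strictly greater than the cutoff."""
    if not (0.0 <= posterior_min <= 1.0):
        raise ValueError("posterior_min outside [0,1]")
    return [s for s in sites if s.posterior > posterior_min]


def overlap_regions(
    sites: Sequence[SelectionSite],
    regions: Sequence[RiskRegion],
    mutation_table: Optional[MutationTable] = None,
    hotspot_min: int = DEFAULT_HOTSPOT_MIN,
) -> OverlapReport:
    """Intersect one gene's selection sites with its risk regions.

    A site is in-region when any region interval contains it (inclusive);
    additionally on-hotspot when its missense count reaches ``hotspot_min``.
    """
    genes = {s.gene for s in sites} | {r.protein_id for r in regions}
    if len(genes) > 1:
        raise ValueError(f"overlap_regions expects a single gene, got {sorted(genes)}")
    gene = genes.pop() if genes else ""
    placements = []
    for site in sites:
        hit = next((r for r in regions if r.contains(site.position)), None)
        count = mutation_table.missense_at(site.position) if mutation_table else 0
        placements.append(
            SitePlacement(
                site=site,
                in_region=hit is not None,
                region_name=hit.name if hit else None,
                missense_count=count,
                on_hotspot=hit is not None and count >= hotspot_min,
            )
        )
    return OverlapReport(
        gene=gene,
        sites_total=len(placements),
        sites_in_region=sum(p.in_region for p in placements),
        sites_on_hotspots=sum(p.on_hotspot for p in placements),
        placements=placements,
    )


def overlap_cohort(
    sites: Iterable[SelectionSite],
    regions: Iterable[RiskRegion],
    mutation_tables: Optional[Mapping[str, MutationTable]] = None,
    posterior_min: float = DEFAULT_POSTERIOR_MIN,
    hotspot_min: int = DEFAULT_HOTSPOT_MIN,
) -> dict[str, OverlapReport]:
    """Per-gene overlap reports for a whole cohort."""
    kept = filter_selection_sites(sites, posterior_min)
    by_gene_sites: dict[str, list[SelectionSite]] = {}
    for s in kept:
        by_gene_sites.setdefault(s.gene, []).append(s)
    by_gene_regions: dict[str, list[RiskRegion]] = {}
    for r in regions:
        by_gene_regions.setdefault(r.protein_id, []).append(r)
    reports = {}
    for gene, gsites in sorted(by_gene_sites.items()):
        table = mutation_tables.get(gene) if mutation_tables else None
        reports[gene] = overlap_regions(
            gsites, by_gene_regions.get(gene, []), table, hotspot_min
        )
    return reports


def join_mk_flags(genes: Iterable[str], mk_flag_table: Mapping[str, bool]) -> set[str]:
    """Genes flagged by the (externally computed) McDonald-Kreitman test.

    Genes absent from the flag table produce a warning, not an error."""
    genes = list(genes)
    unknown = [g for g in genes if g not in mk_flag_table]
    if unknown:
        warnings.warn(f"genes without MK-test entries: {sorted(unknown)}", stacklevel=2)
    return {g for g in genes if mk_flag_table.get(g, False)}
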