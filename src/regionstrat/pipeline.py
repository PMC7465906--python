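"""End-to-end orchestration: align -> conserve -> scan -> age -> classify
-> overlap, with a machine-readable, byte-deterministic report.

``analyze_family`` runs the whole per-family chain; ``run_pipeline`` wraps
either a simulated cohort (scenario presets from :mod:`synthetic_data`),
explicit input files, or an overlap-only join of selection sites against
regions.  Reports serialize to JSON with sorted keys and no timestamps so
that a fixed config + seed reproduces identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import __version__
from .conservation import call_region_conservation
from .emergence import EmergenceResult, classify, summarize_cohort
from .formats_io import (
    AnnotatedGeneTree,
    MutationTable,
    RiskRegion,
    SelectionSite,
    SubstitutionMatrix,
    TaxonomyLadder,
    default_ladder,
    load_paper_fixture,
    load_substitution_matrix,
    read_fasta,
    read_gene_tree,
    read_mutation_tables,
    read_regions,
    read_selection_sites,
)
from .msa import Alignment, import_alignment, progressive_align, project_region
from .phylostrat import assign_gene_age, assign_region_age, lca
from .profile_scan import build_profile, corroborate, scan_sequence
from .selection_overlap import overlap_cohort
from .synthetic_data import SCENARIOS, scenario_config, simulate_family

__all__ = ["RunConfig", "FamilyResult", "RunReport", "analyze_family", "run_pipeline", "render_summaries"]


@dataclass
class RunConfig:
    """One reproducible run.  Exactly one input mode applies:

    * simulation: ``simulate_scenarios`` non-empty (scenario -> n families);
    * files: ``tree_path`` + ``fasta_path`` + ``mutations_path`` + ``regions_path``;
    * overlap-only: ``regions_path``/packaged fixture + ``selection_path``.
    """

    seed: int = 0
    simulate_scenarios: dict[str, int] = field(default_factory=dict)
    tree_path: Optional[str] = None
    fasta_path: Optional[str] = None
    alignment_path: Optional[str] = None  # external alignment, wins over builtin
    mutations_path: Optional[str] = None
    regions_path: Optional[str] = None
    selection_path: Optional[str] = None
    use_paper_fixture: bool = False
    reference_id: Optional[str] = None
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    point_region_flank: int = 7
    min_mutations: int = 1
    posterior_min: float = 0.9
    hotspot_min: int = 15
    output_dir: Optional[str] = None

    def validate(self) -> None:
        for p in (
            self.tree_path,
            self.fasta_path,
            self.alignment_path,
            self.mutations_path,
            self.regions_path,
            self.selection_path,
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        modes = [
            bool(self.simulate_scenarios),
            self.tree_path is not None,
            self.selection_path is not None or self.use_paper_fixture,
        ]
        if not any(modes):
            raise ValueError("config selects no input mode (simulate, files, or overlap)")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class FamilyResult:
    """Everything the pipeline decided about one region/family."""

    family_id: str
    region_name: str
    gene_stratum: str
    region_stratum: str
    emergence_node: str
    age_flags: list[str]
    mechanism: str
    sub_scenario: Optional[str]
    fate: str
    verdicts: dict[str, str]  # homolog -> conserved|not_conserved|conflict
    conservation_fractions: dict[str, float]
    conflicts: list[str]
    truth_region_stratum: Optional[str] = None
    truth_scenario: Optional[str] = None
    truth_fate: Optional[str] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _final_verdicts(
    alignment: Alignment,
    tree: AnnotatedGeneTree,
    region: RiskRegion,
    table: MutationTable,
    reference_id: str,
    matrix: SubstitutionMatrix,
    ladder: TaxonomyLadder,
) -> tuple[dict[str, str], dict[str, float]]:
    """Conservation call per homolog, corroborated by a profile scan when a
    training set (reference + conserved vertebrate-or-younger homologs with
    a gap-free projection) of at least two instances exists."""
    projections = {p.homolog_id: p for p in project_region(alignment, reference_id, region)}
    calls = {
        hid: call_region_conservation(proj, region, table, matrix)
        for hid, proj in projections.items()
    }
    fractions = {hid: c.mutation_weighted_fraction for hid, c in calls.items()}

    vert_idx = ladder.age_index("Vertebrata") if "Vertebrata" in ladder.strata else 0
    ref_node = tree.leaf_by_name(reference_id)
    ref_instance = alignment.ungapped(reference_id)[region.start - 1 : region.end]
    training: list[tuple[str, str]] = [(reference_id, ref_instance)]
    for hid, call in calls.items():
        if not call.conserved:
            continue
        proj = projections[hid]
        if any(h == "-" for _, h in proj.pairs):
            continue
        anc = tree.node(lca(tree, ref_node.id, tree.leaf_by_name(hid).id))
        if ladder.age_index(ladder.stratum_of(anc.taxon_label)) <= vert_idx:
            training.append((hid, proj.homolog_instance()))

    profile = None
    if len(training) >= 2:
        profile = build_profile(training)

    verdicts: dict[str, str] = {}
    for hid, call in calls.items():
        if profile is None:
            verdicts[hid] = "conserved" if call.conserved else "not_conserved"
            continue
        seq = alignment.ungapped(hid)
        if len(seq) < len(profile):
            above = False
        else:
            above = scan_sequence(seq, profile).above_threshold
        verdicts[hid] = corroborate(call.conserved, above)
    return verdicts, fractions


def analyze_family(
    tree: AnnotatedGeneTree,
    sequences: Mapping[str, str],
    table: MutationTable,
    region: RiskRegion,
    reference_id: str,
    ladder: TaxonomyLadder | None = None,
    matrix: SubstitutionMatrix | None = None,
    alignment: Alignment | None = None,
    family_id: str = "family",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> FamilyResult:
    """Run the per-family chain and return the assembled result.

    ``alignment`` (e.g. imported MAFFT output) takes precedence over the
    built-in progressive aligner.
    """
    ladder = ladder or default_ladder()
    matrix = matrix or load_substitution_matrix("BLOSUM62")
    if alignment is None:
        alignment = progressive_align(sequences, tree, matrix, gap_open, gap_extend)
    verdicts, fractions = _final_verdicts(
        alignment, tree, region, table, reference_id, matrix, ladder
    )
    # conflicts resolve to not-conserved before aging (conservative), but are
    # reported so users can emulate the manual-review step
    presence_bool = {hid: v == "conserved" for hid, v in verdicts.items()}
    gene_age = assign_gene_age(tree, ladder)
    region_age = assign_region_age(tree, reference_id, presence_bool, ladder)
    presence_full = dict(presence_bool)
    presence_full[reference_id] = True
    emergence = classify(tree, region_age.node_id, presence_full)
    return FamilyResult(
        family_id=family_id,
        region_name=region.name,
        gene_stratum=gene_age.stratum,
        region_stratum=region_age.stratum,
        emergence_node=region_age.node_id,
        age_flags=region_age.flags,
        mechanism=emergence.mechanism,
        sub_scenario=emergence.sub_scenario,
        fate=emergence.fate,
        verdicts=verdicts,
        conservation_fractions=fractions,
        conflicts=sorted(h for h, v in verdicts.items() if v == "conflict"),
    )


@dataclass
class RunReport:
    config_digest: str
    seed: int
    version: str
    families: list[FamilyResult] = field(default_factory=list)
    stratum_matrix: dict[str, dict[str, int]] = field(default_factory=dict)
    mechanism_counts: dict[str, int] = field(default_factory=dict)
    fate_counts: dict[str, int] = field(default_factory=dict)
    recovery: dict[str, float] = field(default_factory=dict)
    overlap: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "version": self.version,
            "families": [f.to_dict() for f in self.families],
            "stratum_matrix": self.stratum_matrix,
            "mechanism_counts": self.mechanism_counts,
            "fate_counts": self.fate_counts,
            "recovery": self.recovery,
            "overlap": self.overlap,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _scenario_truth_check(results: list[FamilyResult]) -> dict[str, float]:
    """Recovery rates against planted ground truth (simulation mode only)."""
    scored = [r for r in results if r.truth_region_stratum is not None]
    if not scored:
        return {}

    def mech_of(scenario: str) -> tuple[str, Optional[str]]:
        return {
            "neofunctionalization": ("neofunctionalization", None),
            "de_novo_pre_dup": ("de_novo", "pre_duplication"),
            "de_novo_post_dup": ("de_novo", "post_duplication"),
            "singleton": ("singleton", None),
        }[scenario]

    n = len(scored)
    stratum_ok = sum(r.region_stratum == r.truth_region_stratum for r in scored)
    mech_ok = sum(
        (r.mechanism, r.sub_scenario) == mech_of(r.truth_scenario) for r in scored
    )
    fate_ok = sum(r.fate == r.truth_fate for r in scored)
    return {
        "n_families": float(n),
        "region_stratum_recovery": stratum_ok / n,
        "mechanism_recovery": mech_ok / n,
        "fate_recovery": fate_ok / n,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured run and return the report."""
    config.validate()
    ladder = default_ladder()
    matrix = load_substitution_matrix(config.matrix_name)
    report = RunReport(config_digest=config.digest(), seed=config.seed, version=__version__)

    results: list[FamilyResult] = []
    if config.simulate_scenarios:
        for scenario in sorted(config.simulate_scenarios):
            if scenario not in SCENARIOS:
                raise ValueError(f"unknown scenario {scenario!r}")
            n = config.simulate_scenarios[scenario]
            for fam in range(n):
                sim_cfg = scenario_config(scenario, seed=config.seed)
                tree, seqs, table, region, truth = simulate_family(
                    sim_cfg, family_id=fam, matrix=matrix
                )
                res = analyze_family(
                    tree,
                    seqs,
                    table,
                    region,
                    reference_id=region.protein_id,
                    ladder=ladder,
                    matrix=matrix,
                    family_id=f"{scenario}:{fam}",
                    gap_open=config.gap_open,
                    gap_extend=config.gap_extend,
                )
                res.truth_region_stratum = truth.true_region_stratum
                res.truth_scenario = truth.true_scenario
                res.truth_fate = truth.true_fate
                results.append(res)
    elif config.tree_path is not None:
        if not (config.fasta_path and config.mutations_path and config.regions_path):
            raise ValueError("file mode needs tree, fasta, mutations and regions paths")
        tree = read_gene_tree(config.tree_path)
        seqs = read_fasta(config.fasta_path)
        tables = read_mutation_tables(config.mutations_path)
        regions = read_regions(config.regions_path)
        alignment = import_alignment(config.alignment_path) if config.alignment_path else None
        reference = config.reference_id or tree.leaves()[0].leaf_name
        for region in regions:
            if region.protein_id not in tables:
                raise KeyError(f"no mutation table for region {region.name!r}")
            results.append(
                analyze_family(
                    tree,
                    seqs,
                    tables[region.protein_id],
                    region,
                    reference_id=reference,
                    ladder=ladder,
                    matrix=matrix,
                    alignment=alignment,
                    family_id=region.name,
                    gap_open=config.gap_open,
                    gap_extend=config.gap_extend,
                )
            )

    report.families = results
    if results:
        matrix_counts: dict[str, dict[str, int]] = {}
        for r in results:
            row = matrix_counts.setdefault(r.gene_stratum, {})
            row[r.region_stratum] = row.get(r.region_stratum, 0) + 1
        report.stratum_matrix = matrix_counts
        emergence_like = [
            EmergenceResult(r.mechanism, r.sub_scenario, r.fate) for r in results
        ]
        summary = summarize_cohort(emergence_like)
        report.mechanism_counts = summary["mechanism"]
        report.fate_counts = summary["fate"]
        report.recovery = _scenario_truth_check(results)

    # overlap stage
    regions_for_overlap: list[RiskRegion] = []
    sites: list[SelectionSite] = []
    if config.use_paper_fixture:
        regions_for_overlap, sites = load_paper_fixture()
    if config.selection_path:
        sites = read_selection_sites(config.selection_path)
        if config.regions_path:
            regions_for_overlap = read_regions(config.regions_path)
    if sites and regions_for_overlap:
        tables = read_mutation_tables(config.mutations_path) if config.mutations_path else None
        reports = overlap_cohort(
            sites,
            regions_for_overlap,
            tables,
            posterior_min=config.posterior_min,
            hotspot_min=config.hotspot_min,
        )
        report.overlap = {
            gene: {
                "sites_total": rep.sites_total,
                "sites_in_region": rep.sites_in_region,
                "sites_on_hotspots": rep.sites_on_hotspots,
            }
            for gene, rep in reports.items()
        }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.write(outdir / "report.json")
        render_summaries(report, outdir)
    return report


def render_summaries(report: RunReport, outdir: str | Path, plots: bool = False) -> list[Path]:
    """Write cohort summary tables (and optional plots) to ``outdir``.

    Tables: gene-stratum x region-stratum matrix, mechanism and fate
    counts, and the sorted per-family conservation curve (descending mean
    homolog conservation fraction).
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if report.stratum_matrix:
        strata = sorted(
            {s for row in report.stratum_matrix.values() for s in row}
            | set(report.stratum_matrix)
        )
        df = pd.DataFrame(
            [
                [report.stratum_matrix.get(g, {}).get(r, 0) for r in strata]
                for g in strata
            ],
            index=pd.Index(strata, name="gene_stratum"),
            columns=strata,
        )
        p = outdir / "stratum_matrix.tsv"
        df.to_csv(p, sep="\t")
        written.append(p)

    for name, counts in (("mechanism", report.mechanism_counts), ("fate", report.fate_counts)):
        if counts:
            p = outdir / f"{name}_counts.tsv"
            pd.Series(counts, name="count").rename_axis(name).sort_index().to_csv(p, sep="\t")
            written.append(p)

    if report.families:
        rows = [
            (
                f.family_id,
                f.region_name,
                (sum(f.conservation_fractions.values()) / len(f.conservation_fractions))
                if f.conservation_fractions
                else 0.0,
            )
            for f in report.families
        ]
        df = pd.DataFrame(rows, columns=["family_id", "region", "mean_conservation"])
        df = df.sort_values("mean_conservation", ascending=False, kind="mergesort")
        p = outdir / "conservation_sorted.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
        if plots:  # pragma: no cover - optional dependency path
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(6, 3))
            ax.plot(range(len(df)), df["mean_conservation"], marker="s", ms=3, lw=0.8)
            ax.set_xlabel("region rank")
            ax.set_ylabel("mean conservation")
            fig.tight_layout()
            p = outdir / "conservation_sorted.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)

    if report.overlap:
        rows = [
            (g, d["sites_total"], d["sites_in_region"], d["sites_on_hotspots"])
            for g, d in sorted(report.overlap.items())
        ]
        df = pd.DataFrame(
            rows, columns=["gene", "sites_total", "sites_in_region", "sites_on_hotspots"]
        )
        p = outdir / "selection_overlap.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
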