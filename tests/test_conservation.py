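"""The mutation-weighted conservation statistic and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regionstrat import (
    MutationTable,
    RiskRegion,
    call_region_conservation,
    filter_dataset,
    position_similar,
    summarize_region,
)
from regionstrat.msa import Alignment, RegionProjection

from .oracles import oracle_weighted_fraction

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_projection(pairs, homolog_id="hom"):
    return RegionProjection(
        homolog_id=homolog_id,
        columns=list(range(len(pairs))),
        homolog_start=1,
        homolog_end=sum(h != "-" for _, h in pairs) or None,
        pairs=list(pairs),
    )


class TestPositionSimilar:
    def test_conservative_substitution_is_similar(self, blosum):
        assert position_similar("E", "D", blosum)  # BLOSUM62 score 2

    def test_radical_substitution_is_not(self, blosum):
        assert not position_similar("W", "G", blosum)  # score -2

    def test_gap_is_never_similar(self, blosum):
        assert not position_similar("L", "-", blosum)

    def test_ambiguity_code_is_never_similar(self, blosum):
        assert not position_similar("X", "X", blosum)

    def test_invalid_character_is_error(self, blosum):
        with pytest.raises(ValueError):
            position_similar("L", "?", blosum)


class TestRegionCall:
    def test_weighted_fraction_hand_example(self, blosum):
        # counts {10, 4, 1}; homolog similar at positions 1 and 3
        region = RiskRegion(protein_id="ref", start=1, end=3)
        table = MutationTable("ref", missense={1: 10, 2: 4, 3: 1})
        proj = make_projection([("E", "D"), ("W", "G"), ("L", "L")])
        call = call_region_conservation(proj, region, table, blosum)
        assert call.mutation_weighted_fraction == pytest.approx(11 / 15)
        assert call.conserved

    def test_all_identical_is_conserved(self, blosum):
        region = RiskRegion(protein_id="ref", start=1, end=3)
        table = MutationTable("ref", missense={1: 5, 2: 5, 3: 5})
        proj = make_projection([("M", "M"), ("K", "K"), ("V", "V")])
        call = call_region_conservation(proj, region, table, blosum)
        assert call.mutation_weighted_fraction == 1.0
        assert call.conserved

    def test_all_gapped_is_not_conserved(self, blosum):
        region = RiskRegion(protein_id="ref", start=1, end=3)
        table = MutationTable("ref", missense={1: 5, 2: 5, 3: 5})
        proj = make_projection([("M", "-"), ("K", "-"), ("V", "-")])
        call = call_region_conservation(proj, region, table, blosum)
        assert call.mutation_weighted_fraction == 0.0
        assert not call.conserved

    def test_exact_half_split_is_not_conserved(self, blosum):
        # "more than 50%" is strict
        region = RiskRegion(protein_id="ref", start=1, end=2)
        table = MutationTable("ref", missense={1: 5, 2: 5})
        proj = make_projection([("M", "M"), ("W", "G")])
        call = call_region_conservation(proj, region, table, blosum)
        assert call.mutation_weighted_fraction == pytest.approx(0.5)
        assert not call.conserved

    def test_zero_missense_flags_no_weight(self, blosum):
        region = RiskRegion(protein_id="ref", start=1, end=2)
        table = MutationTable("ref", missense={})
        proj = make_projection([("M", "M"), ("K", "K")])
        call = call_region_conservation(proj, region, table, blosum)
        assert call.no_weight
        assert not call.conserved

    def test_projection_length_mismatch_is_error(self, blosum):
        region = RiskRegion(protein_id="ref", start=1, end=3)
        table = MutationTable("ref", missense={1: 1})
        proj = make_projection([("M", "M")])
        with pytest.raises(ValueError, match="pairs"):
            call_region_conservation(proj, region, table, blosum)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(data=st.data())
    def test_matches_brute_force_recount(self, blosum, data):
        n = data.draw(st.integers(min_value=1, max_value=12))
        refs = data.draw(st.lists(st.sampled_from(AA), min_size=n, max_size=n))
        homs = data.draw(st.lists(st.sampled_from(AA + "-"), min_size=n, max_size=n))
        counts = data.draw(
            st.lists(st.integers(min_value=0, max_value=30), min_size=n, max_size=n)
        )
        region = RiskRegion(protein_id="ref", start=1, end=n)
        table = MutationTable("ref", missense={i + 1: c for i, c in enumerate(counts) if c})
        proj = make_projection(list(zip(refs, homs)))
        call = call_region_conservation(proj, region, table, blosum)
        similar = [
            h != "-" and blosum.score(r, h) >= 0 for r, h in zip(refs, homs)
        ]
        assert call.mutation_weighted_fraction == pytest.approx(
            oracle_weighted_fraction(similar, counts)
        )


def random_alignment(rng, n_hom=4, length=10):
    ref = "".join(rng.choice(list(AA), size=length))
    rows = [("ref", ref)]
    for h in range(n_hom):
        hom = [
            "-" if rng.random() < 0.15 else rng.choice(list(AA)) for _ in range(length)
        ]
        rows.append((f"h{h}", "".join(hom)))
    return Alignment(rows)


class TestSummaries:
    def test_identical_homologs_average_one_in_both_modes(self, blosum):
        aln = Alignment([("ref", "MKVL"), ("h1", "MKVL"), ("h2", "MKVL")])
        region = RiskRegion(protein_id="ref", start=1, end=4)
        table = MutationTable("ref", missense={1: 2, 2: 2, 3: 2, 4: 2})
        for mode in ("blosum62", "identity"):
            s = summarize_region(aln, region, table, ["h1", "h2"], "ref", blosum, mode)
            assert s.average_conservation == 1.0

    def test_mode_separation_similar_but_not_identical(self, blosum):
        # E~D, I~V, K~R, S~T: all similar, none identical
        aln = Alignment([("ref", "EIKS"), ("h1", "DVRT")])
        region = RiskRegion(protein_id="ref", start=1, end=4)
        table = MutationTable("ref", missense={1: 1, 2: 1, 3: 1, 4: 1})
        b = summarize_region(aln, region, table, ["h1"], "ref", blosum, "blosum62")
        i = summarize_region(aln, region, table, ["h1"], "ref", blosum, "identity")
        assert b.average_conservation == 1.0
        assert i.average_conservation == 0.0

    def test_min_mutations_filter_hand_example(self, blosum):
        # counts {20, 16, 3, 1}: only the first two positions qualify at 15
        aln = Alignment([("ref", "MKVL"), ("h1", "MKAA")])
        region = RiskRegion(protein_id="ref", start=1, end=4)
        table = MutationTable("ref", missense={1: 20, 2: 16, 3: 3, 4: 1})
        s = summarize_region(
            aln, region, table, ["h1"], "ref", blosum, "identity", min_mutations=15
        )
        assert s.positions_used == 2
        assert s.average_conservation == 1.0  # M and K both identical

    def test_no_qualifying_position_marks_empty(self, blosum):
        aln = Alignment([("ref", "MK"), ("h1", "MK")])
        region = RiskRegion(protein_id="ref", start=1, end=2)
        table = MutationTable("ref", missense={1: 3})
        s = summarize_region(
            aln, region, table, ["h1"], "ref", blosum, min_mutations=25
        )
        assert s.is_empty
        assert s.positions_used == 0

    def test_identity_average_never_exceeds_similarity_average(self, blosum):
        rng = np.random.default_rng(7)
        region = RiskRegion(protein_id="ref", start=1, end=10)
        table = MutationTable("ref", missense={p: 1 for p in range(1, 11)})
        for _ in range(200):
            aln = random_alignment(rng)
            homs = [r for r, _ in aln.rows if r != "ref"]
            b = summarize_region(aln, region, table, homs, "ref", blosum, "blosum62")
            i = summarize_region(aln, region, table, homs, "ref", blosum, "identity")
            assert i.average_conservation <= b.average_conservation + 1e-12

    def test_raising_min_mutations_never_increases_positions_used(self, blosum):
        rng = np.random.default_rng(11)
        aln = random_alignment(rng)
        homs = [r for r, _ in aln.rows if r != "ref"]
        region = RiskRegion(protein_id="ref", start=1, end=10)
        table = MutationTable(
            "ref", missense={p: int(rng.integers(0, 30)) for p in range(1, 11)}
        )
        used = [
            summarize_region(aln, region, table, homs, "ref", blosum, "blosum62", m).positions_used
            for m in (1, 5, 15, 25)
        ]
        assert used == sorted(used, reverse=True)


class TestDatasetFilter:
    def _region(self, pid="P1"):
        return RiskRegion(protein_id=pid, start=1, end=10, name=f"{pid}_r")

    def test_fourteen_missense_excluded(self):
        r = self._region()
        tables = {"P1": MutationTable("P1", missense={1: 14})}
        kept, reasons = filter_dataset([r], tables)
        assert kept == []
        assert "14 missense" in reasons[r.name]

    def test_fifteen_missense_retained(self):
        r = self._region()
        tables = {"P1": MutationTable("P1", missense={1: 15})}
        kept, _ = filter_dataset([r], tables)
        assert kept == [r]

    def test_indel_majority_excluded(self):
        r = self._region()
        tables = {
            "P1": MutationTable("P1", missense={1: 20}, inframe_indel={2: 25})
        }
        kept, reasons = filter_dataset([r], tables)
        assert kept == []
        assert "indel-dominated" in reasons[r.name]

    def test_missing_table_is_error(self):
        with pytest.raises(KeyError):
            filter_dataset([self._region()], {})
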