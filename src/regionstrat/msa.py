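"""Progressive multiple alignment and region projection.

The pipeline needs two things from an aligner: (1) a deterministic multiple
alignment of a homolog set so that (2) a risk region defined on the human
reference can be projected column-wise onto every homolog.  The built-in
aligner is a progressive profile-profile Needleman-Wunsch-Gotoh (global,
affine gaps, sum-of-pairs column scoring, guide-tree post-order merging).
Externally produced alignments (e.g. MAFFT output) can be imported instead
and take precedence when provided.

Conventions
-----------
* gap character is ``-``; a gap of length L costs ``gap_open + L * gap_extend``
  (BLAST-style; defaults 11/1, the canonical BLOSUM62 pairing).
* dynamic-program ties are broken match > delete > insert ("delete" consumes
  a column of the first profile), so alignments are byte-stable across runs.
* residue coordinates are 1-based; half-open arithmetic exists only inside
  this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .formats_io import (
    AMINO_ACIDS,
    AnnotatedGeneTree,
    RiskRegion,
    SubstitutionMatrix,
    parse_functional_unit_bounds,
)

GAP = "-"
_ALPHABET = AMINO_ACIDS + "X"
_AA_INDEX = {a: i for i, a in enumerate(_ALPHABET)}

__all__ = [
    "Alignment",
    "RegionProjection",
    "pairwise_align",
    "progressive_align",
    "import_alignment",
    "project_region",
    "extend_point_region",
]


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------


class Alignment:
    """An ordered set of equal-length gapped rows with coordinate indices.

    ``col_to_res(row_id)[c]`` gives the 1-based residue number at column
    ``c`` (0-based) or 0 for a gap; ``res_to_col`` is its inverse.
    """

    def __init__(self, rows: Sequence[tuple[str, str]]):
        if not rows:
            raise ValueError("alignment has no rows")
        lengths = {len(s) for _, s in rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment rows (lengths {sorted(lengths)})")
        ids = [rid for rid, _ in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")
        self.rows: list[tuple[str, str]] = [(rid, s) for rid, s in rows]
        self.column_count = lengths.pop()
        self._by_id = {rid: s for rid, s in self.rows}
        self._col_to_res: dict[str, np.ndarray] = {}
        self._res_to_col: dict[str, np.ndarray] = {}
        for rid, s in self.rows:
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            isres = arr != ord(GAP)
            c2r = np.where(isres, np.cumsum(isres), 0)
            self._col_to_res[rid] = c2r
            self._res_to_col[rid] = np.flatnonzero(isres)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, row_id: str) -> str:
        try:
            return self._by_id[row_id]
        except KeyError:
            raise KeyError(f"row {row_id!r} not in alignment") from None

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def col_to_res(self, row_id: str) -> np.ndarray:
        self.row(row_id)
        return self._col_to_res[row_id]

    def res_to_col(self, row_id: str, residue: int) -> int:
        """Column (0-based) holding 1-based residue number ``residue``."""
        cols = self._res_to_col[row_id]
        if not (1 <= residue <= len(cols)):
            raise IndexError(f"residue {residue} outside row {row_id!r} (length {len(cols)})")
        return int(cols[residue - 1])


@dataclass
class RegionProjection:
    """A reference region mapped onto one homolog row of an alignment."""

    homolog_id: str
    columns: list[int]
    homolog_start: Optional[int]
    homolog_end: Optional[int]
    pairs: list[tuple[str, str]]  # (ref residue, homolog residue or '-')

    @property
    def is_empty(self) -> bool:
        return self.homolog_start is None

    def homolog_instance(self) -> str:
        """Gapped homolog string over the region columns."""
        return "".join(h for _, h in self.pairs)


# ---------------------------------------------------------------------------
# Profiles and the Gotoh dynamic program
# ---------------------------------------------------------------------------


class _Profile:
    """Gapped rows plus per-column residue counts (gaps contribute nothing
    to column match scores)."""

    __slots__ = ("rows", "counts")

    def __init__(self, rows: list[tuple[str, str]], counts: np.ndarray):
        self.rows = rows
        self.counts = counts  # (ncols, len(_ALPHABET)) float

    @classmethod
    def from_sequence(cls, sid: str, seq: str) -> "_Profile":
        if not seq:
            raise ValueError(f"empty sequence {sid!r}")
        counts = np.zeros((len(seq), len(_ALPHABET)))
        for i, ch in enumerate(seq):
            if ch not in _AA_INDEX:
                raise ValueError(f"non-amino-acid character {ch!r} in sequence {sid!r}")
            counts[i, _AA_INDEX[ch]] = 1.0
        return cls([(sid, seq)], counts)


def _matrix_array(matrix: SubstitutionMatrix) -> np.ndarray:
    m = np.zeros((len(_ALPHABET), len(_ALPHABET)))
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            m[i, j] = matrix.score(a, b)
    return m


_NEG = -1e18


def _gotoh(S: np.ndarray, gap_open: float, gap_extend: float):
    """Global affine-gap DP over a precomputed column-score matrix S (n x m).

    Returns (score, ops) where ops is a list over 'M' (consume both),
    'D' (consume first profile only), 'I' (consume second only), in order.
    """
    n, m = S.shape
    go = gap_open + gap_extend  # cost of the first gapped column
    ge = gap_extend
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in second profile (consume first)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in first profile (consume second)
    M[0, 0] = 0.0
    if m:
        Iy[0, 1:] = -(gap_open + ge * np.arange(1, m + 1))
    jj = np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[i - 1, :] + prev_best[:-1]
        Ix[i] = np.maximum(M[i - 1] - go, Ix[i - 1] - ge)
        # Iy[i, j] = max_{k<j} M[i, k] - gap_open - ge*(j-k): prefix-max trick
        u = M[i] + ge * jj
        Iy[i, 1:] = np.maximum.accumulate(u[:-1]) - gap_open - ge * jj[1:]
    # traceback; ties broken M > Ix (delete) > Iy (insert)
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("D", Ix[n, m]), ("I", Iy[n, m])),
        key=lambda t: (t[1], {"M": 2, "D": 1, "I": 0}[t[0]]),
    )[0]
    score = {"M": M, "D": Ix, "I": Iy}[state][n, m]
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            tgt = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand, mat in (("M", M), ("D", Ix), ("I", Iy)):
                if np.isclose(mat[i, j], tgt, atol=1e-9):
                    state = cand
                    break
        elif state == "D":
            ops.append("D")
            if np.isclose(Ix[i, j], M[i - 1, j] - go, atol=1e-9):
                state = "M"
            else:
                state = "D"
            i -= 1
        else:
            ops.append("I")
            if np.isclose(Iy[i, j], M[i, j - 1] - go, atol=1e-9):
                state = "M"
            else:
                state = "I"
            j -= 1
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "I"
        elif j == 0:
            state = "D"
    ops.reverse()
    return float(score), ops


def _merge(a: _Profile, b: _Profile, B: np.ndarray, gap_open: float, gap_extend: float):
    """Align two profiles and return (merged profile, score)."""
    S = a.counts @ B @ b.counts.T  # sum-of-pairs column scores
    score, ops = _gotoh(S, gap_open, gap_extend)
    na = len(a.rows)
    nb = len(b.rows)
    cols_a: list[int | None] = []
    cols_b: list[int | None] = []
    ia = ib = 0
    for op in ops:
        if op == "M":
            cols_a.append(ia)
            cols_b.append(ib)
            ia += 1
            ib += 1
        elif op == "D":
            cols_a.append(ia)
            cols_b.append(None)
            ia += 1
        else:
            cols_a.append(None)
            cols_b.append(ib)
            ib += 1
    ncols = len(ops)
    counts = np.zeros((ncols, len(_ALPHABET)))
    new_rows: list[tuple[str, str]] = []
    for rid, s in a.rows:
        new_rows.append((rid, "".join(s[c] if c is not None else GAP for c in cols_a)))
    for rid, s in b.rows:
        new_rows.append((rid, "".join(s[c] if c is not None else GAP for c in cols_b)))
    for k, (ca, cb) in enumerate(zip(cols_a, cols_b)):
        if ca is not None:
            counts[k] += a.counts[ca]
        if cb is not None:
            counts[k] += b.counts[cb]
    return _Profile(new_rows, counts), score


def pairwise_align(
    seq_a: tuple[str, str],
    seq_b: tuple[str, str],
    matrix: SubstitutionMatrix,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[Alignment, float]:
    """Global affine-gap alignment of two (id, sequence) pairs."""
    B = _matrix_array(matrix)
    prof, score = _merge(
        _Profile.from_sequence(*seq_a), _Profile.from_sequence(*seq_b), B, gap_open, gap_extend
    )
    return Alignment(prof.rows), score


def progressive_align(
    sequences: Mapping[str, str],
    guide_tree: AnnotatedGeneTree,
    matrix: SubstitutionMatrix,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Alignment:
    """Progressively align ``sequences`` following the guide tree topology.

    Leaves of the guide tree are matched to sequence ids by their
    ``species|protein_id`` name; profiles are merged in post-order.  Every
    sequence must appear in the tree and vice versa.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences to align")
    for sid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence {sid!r}")
    leaf_names = {leaf.leaf_name for leaf in guide_tree.leaves()}
    missing = set(sequences) - leaf_names
    if missing:
        raise ValueError(f"sequences absent from guide tree: {sorted(missing)}")
    B = _matrix_array(matrix)

    def build(node) -> _Profile | None:
        if node.is_leaf:
            if node.leaf_name not in sequences:
                return None
            return _Profile.from_sequence(node.leaf_name, sequences[node.leaf_name])
        prof = None
        for child in node.children:
            sub = build(child)
            if sub is None:
                continue
            prof = sub if prof is None else _merge(prof, sub, B, gap_open, gap_extend)[0]
        return prof

    prof = build(guide_tree.root)
    assert prof is not None
    # restore the caller's row order
    order = {sid: k for k, sid in enumerate(sequences)}
    rows = sorted(prof.rows, key=lambda r: order[r[0]])
    return Alignment(rows)


def import_alignment(path: str | Path) -> Alignment:
    """Load an externally produced aligned FASTA (e.g. MAFFT output)."""
    from Bio import SeqIO

    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"no rows in alignment file {path}")
    return Alignment(rows)


# ---------------------------------------------------------------------------
# Region projection
# ---------------------------------------------------------------------------


def project_region(
    alignment: Alignment, reference_id: str, region: RiskRegion
) -> list[RegionProjection]:
    """Map a reference-defined region onto every other alignment row.

    Gap columns are recorded as gaps, never skipped, so each projection has
    exactly ``len(region)`` residue pairs.
    """
    ref = alignment.ungapped(reference_id)
    if region.end > len(ref):
        raise ValueError(
            f"region {region.start}-{region.end} outside reference {reference_id!r} "
            f"(length {len(ref)})"
        )
    columns = [alignment.res_to_col(reference_id, p) for p in region.positions()]
    ref_row = alignment.row(reference_id)
    projections = []
    for rid, row in alignment.rows:
        if rid == reference_id:
            continue
        c2r = alignment.col_to_res(rid)
        pairs = [(ref_row[c], row[c]) for c in columns]
        residues = [int(c2r[c]) for c in columns if row[c] != GAP]
        if residues:
            proj = RegionProjection(rid, columns, min(residues), max(residues), pairs)
        else:
            proj = RegionProjection(rid, columns, None, None, pairs)
        projections.append(proj)
    return projections


def extend_point_region(region: RiskRegion, sequence_length: int, flank: int = 7) -> RiskRegion:
    """Widen a single-residue hotspot to a usable interval.

    Explicit motif bounds in the functional-unit annotation win; otherwise
    the point is padded by ``flank`` residues each side, clamped to the
    sequence.
    """
    if region.start != region.end:
        raise ValueError("extend_point_region expects a single-residue region")
    if flank < 0:
        raise ValueError("flank must be non-negative")
    bounds = parse_functional_unit_bounds(region.functional_unit)
    if bounds is not None:
        start, end = bounds
    else:
        start = max(1, region.start - flank)
        end = min(sequence_length, region.start + flank)
    return RiskRegion(
        protein_id=region.protein_id,
        start=start,
        end=end,
        name=region.name,
        disorder_flag=region.disorder_flag,
        functional_unit=region.functional_unit,
    )
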