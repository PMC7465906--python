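"""Position-specific profile scan: the second line of evidence.

Disordered sequence is hard to align, so a projection-based conservation
call can be fooled by a spurious alignment.  As a corroborating check, a
gapless log-odds profile (PSSM) is built from the region's conserved
vertebrate instances and slid along each candidate homolog; a hit above a
self-score-calibrated threshold supports the projection call, a miss
contradicts it, and disagreement is surfaced as an explicit conflict that
downstream stages treat as not conserved.

Column score: ``log2(((count_a + pc * bg_a) / (N_col + pc)) / bg_a)`` with
pseudocount weight ``pc`` and background frequencies ``bg`` (uniform by
default).  Columns gapped in a majority of training instances are dropped;
minority gaps count as missing data (they shrink the column's N).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .formats_io import AMINO_ACIDS

GAP = "-"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

__all__ = ["RegionProfile", "ScanHit", "build_profile", "scan_sequence", "corroborate"]

THRESHOLD_FACTOR = 0.6  # threshold = factor * min training self-score


@dataclass
class RegionProfile:
    """Gapless log-odds scoring profile over the 20 standard amino acids."""

    scores: np.ndarray  # (length, 20)
    pseudocount: float
    background: np.ndarray  # (20,)
    training_ids: list[str]
    score_threshold: float
    kept_columns: list[int]  # indices into the original instance columns

    def __len__(self) -> int:
        return self.scores.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scores": self.scores.tolist(),
            "pseudocount": self.pseudocount,
            "background": self.background.tolist(),
            "training_ids": self.training_ids,
            "score_threshold": self.score_threshold,
            "kept_columns": self.kept_columns,
            "alphabet": AMINO_ACIDS,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionProfile":
        payload = json.loads(Path(path).read_text())
        return cls(
            scores=np.asarray(payload["scores"], dtype=float),
            pseudocount=float(payload["pseudocount"]),
            background=np.asarray(payload["background"], dtype=float),
            training_ids=list(payload["training_ids"]),
            score_threshold=float(payload["score_threshold"]),
            kept_columns=list(payload["kept_columns"]),
        )


@dataclass(frozen=True)
class ScanHit:
    offset: int  # 1-based start position of the best window
    score: float
    above_threshold: bool


def _encode(seq: str) -> np.ndarray:
    """Residue indices; unknown characters (X etc.) become -1."""
    return np.array([_AA_INDEX.get(ch, -1) for ch in seq], dtype=int)


def build_profile(
    region_instances: Sequence[tuple[str, str]],
    pseudocount: float = 1.0,
    background: Optional[np.ndarray] = None,
    threshold_factor: float = THRESHOLD_FACTOR,
) -> RegionProfile:
    """Build a log-odds profile from (id, instance) training pairs.

    Instances must share one length (they come from the same alignment
    columns); columns with more than 50% gaps are dropped, minority gaps
    are treated as missing data.
    """
    if len(region_instances) < 2:
        raise ValueError("need at least two training instances")
    lengths = {len(s) for _, s in region_instances}
    if len(lengths) != 1:
        raise ValueError("training instances differ in length")
    length = lengths.pop()
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not np.isclose(background.sum(), 1.0):
        raise ValueError("background must be 20 frequencies summing to 1")
    n = len(region_instances)
    kept: list[int] = []
    cols: list[np.ndarray] = []
    for c in range(length):
        column = [s[c] for _, s in region_instances]
        gaps = sum(ch == GAP for ch in column)
        if gaps * 2 > n:
            continue
        counts = np.zeros(20)
        for ch in column:
            if ch == GAP:
                continue
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
        kept.append(c)
        cols.append(counts)
    if not kept:
        raise ValueError("no columns left after majority-gap dropping")
    counts = np.vstack(cols)  # (L, 20)
    n_eff = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount * background) / (n_eff + pseudocount)
    scores = np.log2(probs / background)
    # calibrate threshold from training self-scores over the kept columns
    self_scores = []
    for sid, s in region_instances:
        enc = _encode("".join(s[c] for c in kept))
        total = 0.0
        for k, idx in enumerate(enc):
            total += scores[k].min() if idx < 0 else scores[k, idx]
        self_scores.append(total)
    threshold = threshold_factor * min(self_scores)
    return RegionProfile(
        scores=scores,
        pseudocount=pseudocount,
        background=background,
        training_ids=[sid for sid, _ in region_instances],
        score_threshold=float(threshold),
        kept_columns=kept,
    )


def scan_sequence(sequence: str, profile: RegionProfile) -> ScanHit:
    """Exhaustive ungapped scan; best window wins, ties go to the smallest
    offset.  Unknown residues score the column minimum (conservative)."""
    L = len(profile)
    if len(sequence) < L:
        raise ValueError(f"sequence (length {len(sequence)}) shorter than profile ({L})")
    enc = _encode(sequence.replace(GAP, ""))
    if len(enc) < L:
        raise ValueError(f"ungapped sequence shorter than profile ({L})")
    col_min = profile.scores.min(axis=1)
    n_windows = len(enc) - L + 1
    # per-position score contribution for each profile column
    best_score = -np.inf
    best_offset = 0
    scores = np.zeros(n_windows)
    for k in range(L):
        col = profile.scores[k]
        idx = enc[k : k + n_windows]
        contrib = np.where(idx >= 0, col[np.clip(idx, 0, None)], col_min[k])
        scores += contrib
    best_offset = int(np.argmax(scores))  # argmax takes the first maximum
    best_score = float(scores[best_offset])
    return ScanHit(
        offset=best_offset + 1,
        score=best_score,
        above_threshold=best_score >= profile.score_threshold,
    )


def corroborate(projection_conserved: bool, above_threshold: bool) -> str:
    """Combine the alignment-based call with the profile-scan evidence."""
    if projection_conserved and above_threshold:
        return "conserved"
    if not projection_conserved and not above_threshold:
        return "not_conserved"
    return "conflict"
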