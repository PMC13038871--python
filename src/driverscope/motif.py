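"""PWM promoter scanning with exact log-odds p-values.

Each motif is scored as a log2 odds sum (PWM probability over background)
at every window position on both strands; significance comes from the
EXACT null distribution of the integerized score under the background
model, computed by dynamic programming over the motif columns (the FIMO
construction).  A window is a hit when P(score >= s | background) is below
the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .communication import PromoterSet
from .io import PositionWeightMatrix

__all__ = ["MotifHitTable", "scan_motifs", "score_distribution"]

UNIFORM_BACKGROUND = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
INT_SCALE = 1000  # integerization bounds rounding error below 1e-3 bits/position
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PROB_FLOOR = 1e-9


@dataclass
class MotifHitTable:
    hits: pd.DataFrame  # gene, motif_id, offset, strand, score_bits, p_value
    p_threshold: float


def _log_odds_int(pwm: PositionWeightMatrix, bg: np.ndarray) -> np.ndarray:
    """4 x width integerized log2-odds matrix (scale INT_SCALE)."""
    probs = np.clip(pwm.probs, _PROB_FLOOR, None)
    lods = np.log2(probs / bg[:, None])
    return np.round(lods * INT_SCALE).astype(np.int64)


def score_distribution(int_matrix: np.ndarray, bg: np.ndarray) -> tuple[int, np.ndarray]:
    """Exact null pmf of the integer score under the background model.

    Returns (minimum achievable score, pmf array) where ``pmf[i]`` is the
    probability of score ``minimum + i`` for a random background window.
    """
    dist = np.array([1.0])
    total_min = 0
    for j in range(int_matrix.shape[1]):
        col = int_matrix[:, j]
        cmin, cmax = int(col.min()), int(col.max())
        new = np.zeros(len(dist) + (cmax - cmin))
        for b in range(4):
            shift = int(col[b]) - cmin
            new[shift : shift + len(dist)] += dist * bg[b]
        dist = new
        total_min += cmin
    return total_min, dist


def _tail_lookup(total_min: int, pmf: np.ndarray):
    """P(score >= s) as a function of the integer score s."""
    tail = np.cumsum(pmf[::-1])[::-1]

    def p_of(s: int) -> float:
        idx = s - total_min
        if idx <= 0:
            return 1.0
        if idx >= len(tail):
            return 0.0
        return float(tail[idx])

    return p_of


def _window_scores(seq: str, int_matrix: np.ndarray) -> np.ndarray:
    """Integer score at every window start; N bases contribute 0."""
    w = int_matrix.shape[1]
    n = len(seq) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    codes = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)
    scores = np.zeros(n, dtype=np.int64)
    for j in range(w):
        col = int_matrix[:, j]
        c = codes[j : j + n]
        contrib = np.where(c >= 0, col[np.clip(c, 0, 3)], 0)
        scores += contrib
    return scores


def scan_motifs(
    promoters: PromoterSet | Mapping[str, str],
    pwms: Sequence[PositionWeightMatrix],
    background: Mapping[str, float] | None = None,
    p_threshold: float = 0.01,
) -> MotifHitTable:
    """Scan promoter sequences for PWM hits on both strands.

    Reverse-strand hits score the reverse-complement PWM against the
    forward sequence; the reported offset is always relative to the
    forward sequence start.  Sequences shorter than a motif yield zero
    hits for it.  Background base frequencies must sum to 1 (+/- 1e-6).
    """
    seqs = promoters.sequences if isinstance(promoters, PromoterSet) else dict(promoters)
    bg_map = dict(background) if background is not None else dict(UNIFORM_BACKGROUND)
    bg = np.array([bg_map.get(b, 0.0) for b in "ACGT"], dtype=float)
    if abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    if (bg <= 0).any():
        raise ValueError("background frequencies must be positive")

    rows = []
    for pwm in pwms:
        for strand, matrix in (("+", pwm), ("-", pwm.reverse_complement())):
            int_matrix = _log_odds_int(matrix, bg)
            total_min, pmf = score_distribution(int_matrix, bg)
            p_of = _tail_lookup(total_min, pmf)
            for name, seq in seqs.items():
                for off, s in enumerate(_window_scores(seq.upper(), int_matrix)):
                    p = p_of(int(s))
                    if p < p_threshold:
                        rows.append(
                            (name, pwm.motif_id, off, strand, s / INT_SCALE, p)
                        )
    hits = pd.DataFrame(
        rows, columns=["gene", "motif_id", "offset", "strand", "score_bits", "p_value"]
    )
    hits = hits.sort_values(
        ["gene", "motif_id", "offset", "strand"], kind="stable"
    ).reset_index(drop=True)
    return MotifHitTable(hits=hits, p_threshold=p_threshold)
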