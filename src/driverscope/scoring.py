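"""Rank-based gene-set activity scoring.

Two estimators are provided:

* :func:`ssgsea_scores` — single-sample gene-set enrichment.  Per sample,
  genes are ranked by expression (descending, ties broken by gene id); the
  enrichment score is the integral of the running sum that steps up by a
  rank-weighted increment at in-set genes and down by a uniform decrement
  elsewhere.  Normalized scores (NES) rescale the whole ES matrix by its
  global range.
* :func:`aucell_scores` — per-cell area under the set-gene recovery curve
  within the top fraction of the cell's ranking, normalized so a set fully
  occupying the top ranks scores 1.

Both are purely rank-based, hence invariant to any strictly monotone
transformation of a sample's expression column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["PathwayScoreMatrix", "CellSignatureScores", "ssgsea_scores", "aucell_scores"]


@dataclass
class PathwayScoreMatrix:
    """Per-sample enrichment (ES) and normalized (NES) scores per gene set."""

    es: pd.DataFrame  # gene sets x samples
    nes: pd.DataFrame
    weight_exponent: float

    def __post_init__(self) -> None:
        if not self.es.index.equals(self.nes.index) or not self.es.columns.equals(
            self.nes.columns
        ):
            raise ValueError("es and nes must share axes")


@dataclass
class CellSignatureScores:
    """Per-cell recovery-curve scores in [0, 1] per gene set."""

    scores: pd.DataFrame  # gene sets x cells
    top_fraction: float

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("AUCell scores must lie in [0, 1]")


def _rank_order(column: pd.Series) -> np.ndarray:
    """Indices ordering a column by descending expression, ties broken by
    ascending gene id (lexicographic)."""
    order = np.lexsort((column.index.to_numpy(), -column.to_numpy()))
    return order


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    weight_exponent: float = 0.25,
    min_overlap: int = 5,
) -> PathwayScoreMatrix:
    """Single-sample GSEA enrichment scores.

    Per sample the gene with the highest expression receives rank value G
    (the universe size) and the lowest 1; an in-set gene at a position with
    rank value r contributes a hit increment proportional to r**alpha, and
    every out-of-set gene a uniform miss decrement.  ES is the sum of the
    running sum over all positions.  NES divides every ES by the range
    (max - min) of the full ES matrix.

    Sets sharing fewer than ``min_overlap`` genes with the matrix are
    skipped with a warning; an empty collection (or one with no usable set)
    is an error.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    genes = expr.gene_ids
    universe = set(genes)
    usable = {}
    for gs in sets:
        overlap = [g for g in gs.genes if g in universe]
        if len(overlap) < max(min_overlap, 1):
            logger.warning(
                "set %r skipped: overlap %d < %d", gs.name, len(overlap), min_overlap
            )
            continue
        usable[gs.name] = np.asarray(genes.isin(overlap))
    if not usable:
        raise ValueError("no gene set overlaps the expression matrix")

    G = len(genes)
    n_samples = expr.shape[1]
    es = np.zeros((len(usable), n_samples))
    set_names = list(usable)
    rank_values = np.arange(G, 0, -1, dtype=float)  # G .. 1 along the ordering
    for j, sample in enumerate(expr.sample_ids):
        order = _rank_order(expr.values[sample])
        weights = rank_values**weight_exponent
        for i, name in enumerate(set_names):
            in_set = usable[name][order]
            hit_w = np.where(in_set, weights, 0.0)
            hit_total = hit_w.sum()
            n_miss = G - int(in_set.sum())
            hit_cdf = np.cumsum(hit_w) / hit_total
            miss_cdf = np.cumsum(np.where(in_set, 0.0, 1.0)) / n_miss
            es[i, j] = float(np.sum(hit_cdf - miss_cdf))

    es_df = pd.DataFrame(es, index=set_names, columns=expr.sample_ids)
    rng_span = float(es.max() - es.min())
    if rng_span == 0.0:
        nes_df = es_df.copy()
    else:
        nes_df = es_df / rng_span
    return PathwayScoreMatrix(es=es_df, nes=nes_df, weight_exponent=weight_exponent)


def aucell_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    top_fraction: float = 0.05,
) -> CellSignatureScores:
    """Area under the set-gene recovery curve within the top ranks.

    With universe size G and cutoff ``n_top = ceil(top_fraction * G)``, the
    recovery curve counts set genes among the top i ranks for i = 1..n_top;
    the score is its area divided by the maximum attainable area (all set
    genes at the very top).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    genes = expr.gene_ids
    gene_set_masks = {}
    universe = set(genes)
    for gs in sets:
        if len(gs.genes) > len(genes):
            raise ValueError(
                f"set {gs.name!r} ({len(gs.genes)} genes) larger than universe ({len(genes)})"
            )
        gene_set_masks[gs.name] = np.asarray(genes.isin([g for g in gs.genes if g in universe]))

    G = len(genes)
    n_top = math.ceil(top_fraction * G)
    set_names = list(gene_set_masks)
    scores = np.zeros((len(set_names), expr.shape[1]))
    for j, sample in enumerate(expr.sample_ids):
        order = _rank_order(expr.values[sample])
        top = order[:n_top]
        for i, name in enumerate(set_names):
            m = int(gene_set_masks[name].sum())
            if m == 0:
                continue
            hits = np.cumsum(gene_set_masks[name][top])
            max_area = np.minimum(np.arange(1, n_top + 1), m).sum()
            scores[i, j] = float(hits.sum()) / float(max_area)
    return CellSignatureScores(
        scores=pd.DataFrame(scores, index=set_names, columns=expr.sample_ids),
        top_fraction=top_fraction,
    )
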