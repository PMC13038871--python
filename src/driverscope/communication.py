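"""Cell-cell communication scoring and promoter extraction.

Ligand-receptor interaction between annotated cell groups is scored as the
product of the sender-group ligand mean and the receiver-group receptor
mean, against a null obtained by permuting group labels across all cells.
A pair is significant when the permutation p-value is below 0.05 AND the
ligand is more than 2-fold enriched in the sender (log2FC > 1).

Also here: the composite receptor-to-TF axis score (mean of min-max-scaled
axis-gene expression per cell) and strand-aware promoter window extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "LrScoreTable",
    "AxisScoreVector",
    "PromoterSet",
    "lr_permutation_test",
    "axis_score",
    "extract_promoters",
]

_LOGFC_EPS = 1e-9

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LrScoreTable:
    table: pd.DataFrame  # per pair: score, p, ligand_log2fc, significant
    sender: str
    receiver: str
    n_permutations: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def lr_permutation_test(
    expr: ExpressionMatrix,
    cell_groups: pd.Series,
    lr_pairs: list[tuple[str, str]],
    sender: str,
    receiver: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> LrScoreTable:
    """Permutation test for ligand-receptor interaction scores.

    Observed score = mean ligand expression in the sender group times mean
    receptor expression in the receiver group.  The null permutes group
    labels over all cells; p uses the add-one estimator
    (1 + #{null >= observed}) / (1 + n_permutations), so it is never 0.
    Pairs whose ligand or receptor is absent are skipped with a warning.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    groups = cell_groups.loc[expr.sample_ids]
    send_mask = (groups == sender).to_numpy()
    recv_mask = (groups == receiver).to_numpy()
    if send_mask.sum() == 0 or recv_mask.sum() == 0:
        raise ValueError("sender and receiver groups must be non-empty")

    usable = []
    for lig, rec in lr_pairs:
        if lig not in expr.gene_ids or rec not in expr.gene_ids:
            logger.warning("pair (%s, %s) skipped: gene missing", lig, rec)
            continue
        usable.append((lig, rec))
    if not usable:
        raise ValueError("no ligand-receptor pair with both genes present")

    rng = np.random.default_rng(seed)
    lig_expr = expr.values.loc[[p[0] for p in usable]].to_numpy(float)
    rec_expr = expr.values.loc[[p[1] for p in usable]].to_numpy(float)
    observed = lig_expr[:, send_mask].mean(axis=1) * rec_expr[:, recv_mask].mean(axis=1)

    exceed = np.zeros(len(usable))
    n_cells = expr.shape[1]
    n_send, n_recv = int(send_mask.sum()), int(recv_mask.sum())
    for _ in range(n_permutations):
        # Permuting labels over all cells = drawing disjoint random index
        # blocks of the two group sizes from one permutation.
        perm = rng.permutation(n_cells)
        null = (
            lig_expr[:, perm[:n_send]].mean(axis=1)
            * rec_expr[:, perm[n_send : n_send + n_recv]].mean(axis=1)
        )
        exceed += null >= observed
    p = (1.0 + exceed) / (1.0 + n_permutations)

    lig_sender = lig_expr[:, send_mask].mean(axis=1)
    lig_other = lig_expr[:, ~send_mask].mean(axis=1)
    log2fc = np.log2((lig_sender + _LOGFC_EPS) / (lig_other + _LOGFC_EPS))
    table = pd.DataFrame(
        {
            "ligand": [p_[0] for p_ in usable],
            "receptor": [p_[1] for p_ in usable],
            "score": observed,
            "p": p,
            "ligand_log2fc": log2fc,
            "significant": (p < 0.05) & (log2fc > 1.0),
        }
    ).set_index(["ligand", "receptor"])
    return LrScoreTable(
        table=table, sender=sender, receiver=receiver, n_permutations=n_permutations
    )


@dataclass
class AxisScoreVector:
    scores: pd.Series  # per cell, in [0, 1]
    axis_genes: tuple[str, ...]
    dropped_genes: tuple[str, ...]
    scaling: str = "min-max per gene"


def axis_score(expr: ExpressionMatrix, axis_genes: list[str]) -> AxisScoreVector:
    """Composite axis activity: per cell, the mean of min-max-scaled
    expression over the available axis genes.

    Genes absent from the matrix, or with a degenerate (constant) range,
    are dropped and recorded.
    """
    present, dropped = [], []
    for g in axis_genes:
        if g not in expr.gene_ids:
            dropped.append(g)
            continue
        row = expr.values.loc[g]
        if float(row.max() - row.min()) == 0.0:
            dropped.append(g)
            continue
        present.append(g)
    if not present:
        raise ValueError("no usable axis gene present in the matrix")
    sub = expr.values.loc[present]
    lo = sub.min(axis=1)
    span = sub.max(axis=1) - lo
    scaled = sub.sub(lo, axis=0).div(span, axis=0)
    return AxisScoreVector(
        scores=scaled.mean(axis=0).rename("axis_score"),
        axis_genes=tuple(present),
        dropped_genes=tuple(dropped),
    )


@dataclass
class PromoterSet:
    sequences: dict[str, str]  # gene -> promoter sequence (TSS-oriented)
    coordinates: pd.DataFrame  # gene_id, chrom, start, end, strand
    upstream: int
    downstream: int


def extract_promoters(
    annotation: GenomeAnnotation,
    genome: dict[str, str],
    upstream: int = 1000,
    downstream: int = 100,
) -> PromoterSet:
    """Strand-aware promoter windows around each gene's TSS.

    Plus strand: window [TSS - upstream, TSS + downstream) with TSS = gene
    start.  Minus strand: TSS = gene end, window [TSS - downstream,
    TSS + upstream), sequence reverse-complemented so that it reads
    upstream-to-downstream.  Windows truncate at contig bounds; genes on
    missing contigs are skipped with a warning.
    """
    seqs: dict[str, str] = {}
    rows = []
    for rec in annotation.records.itertuples():
        if rec.chrom not in genome:
            logger.warning("gene %r skipped: contig %r missing", rec.gene_id, rec.chrom)
            continue
        contig = genome[rec.chrom]
        if rec.strand == "+":
            tss = rec.start
            lo, hi = max(0, tss - upstream), min(len(contig), tss + downstream)
            seq = contig[lo:hi]
        else:
            tss = rec.end
            lo, hi = max(0, tss - downstream), min(len(contig), tss + upstream)
            seq = _revcomp(contig[lo:hi])
        if not seq:
            continue
        seqs[rec.gene_id] = seq
        rows.append((rec.gene_id, rec.chrom, lo, hi, rec.strand))
    coords = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return PromoterSet(
        sequences=seqs, coordinates=coords, upstream=upstream, downstream=downstream
    )
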