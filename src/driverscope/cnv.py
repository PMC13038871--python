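"""Single-cell QC and reference-anchored CNV malignancy calling.

The copy-number surrogate follows the inferCNV-style recipe: subtract the
reference (non-malignant) mean per gene from log-normalized expression,
clamp residuals, and smooth with a running mean over a genomically ordered
window of genes within each chromosome.  Focal events at driver genes are
called from robust Z-scores (median / scaled MAD of the reference), and
clusters are labeled tumor-like when their aggregate CNV burden or driver
event fraction exceeds the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "QcThresholds",
    "CnvProfileMatrix",
    "FocalCallMatrix",
    "ClusteringSolution",
    "MalignancyLabels",
    "qc_filter_cells",
    "infer_cnv_profile",
    "call_focal_events",
    "select_resolution",
    "label_malignant",
    "knn_graph",
    "leiden_partitioner",
]

MAD_SCALE = 1.4826  # consistency constant for a normal distribution
MAD_EPSILON = 1e-6


@dataclass(frozen=True)
class QcThresholds:
    """Cell-level quality-control cutoffs."""

    min_genes: int = 200
    max_genes: int = 10000
    max_mito_fraction: float = 0.20
    max_hemoglobin_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        for f in (self.max_mito_fraction, self.max_hemoglobin_fraction):
            if not 0 < f <= 1:
                raise ValueError("fractions must be in (0, 1]")


def qc_filter_cells(
    counts: ExpressionMatrix,
    mito_genes: Sequence[str] = (),
    hb_genes: Sequence[str] = (),
    thresholds: QcThresholds = QcThresholds(),
    filter_genes: bool = True,
    min_cells_per_gene: int = 50,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove low-quality cells (and sparsely detected genes).

    A cell passes when its detected-gene count lies in
    [min_genes, max_genes] and its mitochondrial / hemoglobin count
    fractions do not exceed their cutoffs.  With ``filter_genes``, genes
    detected in fewer than ``min_cells_per_gene`` of the surviving cells
    are dropped.  Returns the filtered matrix and a per-cell QC report.
    """
    if counts.mode != "counts":
        raise ValueError("QC operates on raw counts")
    mat = counts.values
    detected = (mat > 0).sum(axis=0)
    total = mat.sum(axis=0).astype(float)
    total_safe = total.replace(0, np.nan)
    mito = mat.loc[mat.index.intersection(list(mito_genes))].sum(axis=0) / total_safe
    hb = mat.loc[mat.index.intersection(list(hb_genes))].sum(axis=0) / total_safe
    mito = mito.fillna(0.0)
    hb = hb.fillna(0.0)
    keep = (
        (detected >= thresholds.min_genes)
        & (detected <= thresholds.max_genes)
        & (mito <= thresholds.max_mito_fraction)
        & (hb <= thresholds.max_hemoglobin_fraction)
    )
    report = pd.DataFrame(
        {
            "n_genes_detected": detected,
            "total_counts": total,
            "mito_fraction": mito,
            "hb_fraction": hb,
            "pass": keep,
        }
    )
    if not keep.any():
        raise ValueError("quality control removed every cell")
    filtered = mat.loc[:, keep]
    if filter_genes:
        gene_keep = (filtered > 0).sum(axis=1) >= min_cells_per_gene
        filtered = filtered.loc[gene_keep]
    return ExpressionMatrix(filtered.copy(), mode="counts"), report


# ---------------------------------------------------------------------------
# CNV profile
# ---------------------------------------------------------------------------


@dataclass
class CnvProfileMatrix:
    """Cells x genes reference-centered, windowed copy-number deviations."""

    smoothed: pd.DataFrame  # cells x genes, genomic gene order
    window: int
    cnv_score: pd.Series  # per-cell mean of squared smoothed deviations
    reference_cells: tuple[str, ...]
    gene_order: pd.DataFrame  # gene_id, chrom, start (sorted)


def infer_cnv_profile(
    expr: ExpressionMatrix,
    annotation: GenomeAnnotation,
    reference_cells: Sequence[str],
    window: int = 100,
    clamp: float = 3.0,
    min_genes_per_chrom: int = 10,
) -> CnvProfileMatrix:
    """Sliding-window CNV surrogate from log-normalized expression.

    Genes are placed in (chrom, start) order; per gene the reference-cell
    mean is subtracted, residuals are clamped to +/- ``clamp``, and a
    centered running mean over ``window`` genes is taken within each
    chromosome (windows truncate at chromosome ends; chromosomes with
    fewer than ``min_genes_per_chrom`` annotated genes are excluded).
    """
    reference_cells = [c for c in reference_cells if c in expr.sample_ids]
    if not reference_cells:
        raise ValueError("empty reference cell set")
    ordered = annotation.genomic_order()
    ordered = ordered[ordered["gene_id"].isin(expr.gene_ids)]
    chrom_sizes = ordered.groupby("chrom", sort=False).size()
    small = chrom_sizes[chrom_sizes < min_genes_per_chrom].index
    for c in small:
        logger.warning("chromosome %s excluded: < %d annotated genes", c, min_genes_per_chrom)
    ordered = ordered[~ordered["chrom"].isin(small)].reset_index(drop=True)
    if len(ordered) == 0:
        raise ValueError("no chromosome retains enough annotated genes")

    genes = ordered["gene_id"].tolist()
    x = expr.values.loc[genes]  # genes x cells
    ref_mean = x[reference_cells].mean(axis=1)
    resid = x.sub(ref_mean, axis=0).clip(-clamp, clamp)

    smoothed_parts = []
    for chrom, block in ordered.groupby("chrom", sort=False):
        part = resid.loc[block["gene_id"]]
        sm = part.rolling(window, center=True, min_periods=1).mean()
        smoothed_parts.append(sm)
    smoothed = pd.concat(smoothed_parts).T  # cells x genes
    cnv_score = (smoothed**2).mean(axis=1)
    cnv_score.name = "cnv_score"
    return CnvProfileMatrix(
        smoothed=smoothed,
        window=window,
        cnv_score=cnv_score,
        reference_cells=tuple(reference_cells),
        gene_order=ordered[["gene_id", "chrom", "start"]],
    )


# ---------------------------------------------------------------------------
# Focal event calls
# ---------------------------------------------------------------------------


@dataclass
class FocalCallMatrix:
    z: pd.DataFrame  # cells x driver genes, robust Z
    calls: pd.DataFrame  # cells x driver genes in {gain, loss, neutral}
    z_gain: float
    z_loss: float
    missing_genes: tuple[str, ...]


def call_focal_events(
    profile: CnvProfileMatrix,
    driver_genes: Sequence[str],
    z_gain: float = 2.0,
    z_loss: float = 2.0,
) -> FocalCallMatrix:
    """Robust-Z focal gain/loss calls at driver genes.

    Per driver gene the reference cells' smoothed values give a median m
    and a MAD scaled by 1.4826 (floored at 1e-6); each cell's
    Z = (value - m) / scaled MAD is thresholded into gain (Z >= z_gain),
    loss (Z <= -z_loss) or neutral.  Drivers absent from the profile are
    reported as missing, not fatal.
    """
    present = [g for g in driver_genes if g in profile.smoothed.columns]
    missing = tuple(g for g in driver_genes if g not in profile.smoothed.columns)
    for g in missing:
        logger.warning("driver gene %r absent from CNV profile", g)
    if not present:
        raise ValueError("no driver gene present in the CNV profile")
    ref = profile.smoothed.loc[list(profile.reference_cells), present]
    med = ref.median(axis=0)
    mad = (ref - med).abs().median(axis=0) * MAD_SCALE
    mad = mad.clip(lower=MAD_EPSILON)
    z = (profile.smoothed[present] - med) / mad
    calls = pd.DataFrame("neutral", index=z.index, columns=z.columns)
    calls = calls.mask(z >= z_gain, "gain").mask(z <= -z_loss, "loss")
    return FocalCallMatrix(
        z=z, calls=calls, z_gain=z_gain, z_loss=z_loss, missing_genes=missing
    )


# ---------------------------------------------------------------------------
# Resolution selection
# ---------------------------------------------------------------------------


@dataclass
class ClusteringSolution:
    grid: tuple[float, ...]
    partitions: dict[float, pd.Series]  # resolution -> per-point labels
    silhouettes: dict[float, float]
    chosen_resolution: float

    @property
    def chosen_partition(self) -> pd.Series:
        return self.partitions[self.chosen_resolution]


def knn_graph(embedding: pd.DataFrame, k: int = 15):
    """Symmetric k-nearest-neighbor adjacency (binary, scipy sparse) on the
    supplied low-dimensional coordinates."""
    from sklearn.neighbors import kneighbors_graph

    k = min(k, len(embedding) - 1)
    adj = kneighbors_graph(embedding.to_numpy(float), n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T)
    return adj


def leiden_partitioner(adjacency, resolution: float, seed: int) -> np.ndarray:
    """Default graph-clustering backend: Leiden with the RB-configuration
    quality function.  Conforms to the injectable partitioner contract
    (adjacency, resolution, seed) -> integer labels."""
    import igraph as ig
    import leidenalg

    coo = adjacency.tocoo()
    edges = [(int(i), int(j)) for i, j in zip(coo.row, coo.col) if i < j]
    graph = ig.Graph(n=adjacency.shape[0], edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=float(resolution),
        seed=int(seed),
    )
    return np.asarray(part.membership)


def select_resolution(
    embedding: pd.DataFrame,
    neighbor_graph,
    grid: Sequence[float] = tuple(np.round(np.arange(0.2, 2.01, 0.1), 2)),
    seed: int = 0,
    partitioner: Callable[[object, float, int], np.ndarray] = leiden_partitioner,
) -> ClusteringSolution:
    """Silhouette-guided resolution sweep for graph clustering.

    Runs the (injectable, seeded) partitioner at each resolution on the
    supplied neighbor graph and scores each partition by the Euclidean
    silhouette on the supplied embedding; single-cluster partitions score
    -1.  Returns the argmax, ties broken toward the smallest resolution.
    """
    from sklearn.metrics import silhouette_score

    if len(embedding) < 3:
        raise ValueError("need >= 3 points")
    if len(grid) == 0:
        raise ValueError("empty resolution grid")
    coords = embedding.to_numpy(float)
    if np.allclose(coords, coords[0]):
        raise ValueError("all embedding points identical")

    partitions, silhouettes = {}, {}
    for res in grid:
        labels = np.asarray(partitioner(neighbor_graph, float(res), int(seed)))
        partitions[float(res)] = pd.Series(labels, index=embedding.index, name="cluster")
        if len(np.unique(labels)) < 2:
            silhouettes[float(res)] = -1.0
        else:
            silhouettes[float(res)] = float(silhouette_score(coords, labels))
    best = max(sorted(silhouettes), key=lambda r: (silhouettes[r], -r))
    return ClusteringSolution(
        grid=tuple(float(r) for r in grid),
        partitions=partitions,
        silhouettes=silhouettes,
        chosen_resolution=best,
    )


# ---------------------------------------------------------------------------
# Malignancy labels
# ---------------------------------------------------------------------------


@dataclass
class MalignancyLabels:
    labels: pd.Series  # per-cell: tumor-like / normal-like / reference
    cluster_evidence: pd.DataFrame  # per-cluster mean score, driver fraction, verdict


def label_malignant(
    profile: CnvProfileMatrix,
    clusters: pd.Series,
    calls: FocalCallMatrix,
    score_z: float = 2.0,
    driver_fraction: float = 0.3,
) -> MalignancyLabels:
    """Tumor-like vs normal-like cluster labeling.

    Reference cells always receive the label "reference".  A cluster of
    query cells is tumor-like when its mean CNV score exceeds the
    reference mean by at least ``score_z`` reference standard deviations,
    OR at least ``driver_fraction`` of its cells carry any non-neutral
    driver call.
    """
    ref = set(profile.reference_cells)
    query = [c for c in profile.smoothed.index if c not in ref]
    uncovered = [c for c in query if c not in clusters.index]
    if uncovered:
        raise ValueError(f"clusters do not cover {len(uncovered)} query cells")
    if clusters.loc[query].nunique() == 0:
        raise ValueError("no clusters supplied")

    ref_scores = profile.cnv_score.loc[list(ref)]
    ref_mean, ref_sd = float(ref_scores.mean()), float(ref_scores.std(ddof=0))
    any_event = (calls.calls != "neutral").any(axis=1)

    labels = pd.Series("reference", index=profile.smoothed.index, name="label")
    rows = []
    for cl, members in clusters.loc[query].groupby(clusters.loc[query]):
        cells = members.index
        mean_score = float(profile.cnv_score.loc[cells].mean())
        frac = float(any_event.reindex(cells).fillna(False).mean())
        tumor = (mean_score >= ref_mean + score_z * ref_sd) or (frac >= driver_fraction)
        labels.loc[cells] = "tumor-like" if tumor else "normal-like"
        rows.append((cl, len(cells), mean_score, frac, "tumor-like" if tumor else "normal-like"))
    evidence = pd.DataFrame(
        rows, columns=["cluster", "n_cells", "mean_cnv_score", "driver_event_fraction", "verdict"]
    ).set_index("cluster")
    return MalignancyLabels(labels=labels, cluster_evidence=evidence)
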