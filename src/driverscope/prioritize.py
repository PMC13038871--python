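"""Driver-candidate prioritization.

Differential expression at single-cell and bulk thresholds, diffusion
pseudotime with per-gene trend tests, and the four-way evidence
intersection that nominates driver candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialExpressionTable",
    "PseudotimeResult",
    "TrendTable",
    "CandidateEvidenceTable",
    "differential_expression",
    "diffusion_pseudotime",
    "trend_test",
    "intersect_candidates",
]

# mode -> (max q, min |log2FC|)
DE_THRESHOLDS = {"single_cell": (0.05, 1.0), "bulk": (0.05, 0.5)}


@dataclass
class DifferentialExpressionTable:
    table: pd.DataFrame  # per gene: log2fc, t, p, q, passed
    mode: str

    @property
    def passed(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])


def differential_expression(
    expr: ExpressionMatrix, group_labels: pd.Series, mode: str = "single_cell"
) -> DifferentialExpressionTable:
    """Welch two-sided t-test per gene on log-scale expression.

    ``group_labels`` holds exactly two levels over the matrix columns; the
    log2 fold change is the difference of group means (first level minus
    second, on the log2 scale the input is assumed to be on).  Passing
    genes satisfy the mode's joint threshold: single_cell q < 0.05 and
    |log2FC| > 1; bulk q < 0.05 and |log2FC| > 0.5.
    """
    if mode not in DE_THRESHOLDS:
        raise ValueError(f"unknown mode {mode!r}")
    labels = group_labels.loc[expr.sample_ids]
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {len(levels)}")
    a = expr.values.loc[:, (labels == levels[0]).to_numpy()].to_numpy(float)
    b = expr.values.loc[:, (labels == levels[1]).to_numpy()].to_numpy(float)
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("each group needs >= 3 observations")
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(t)
    # Zero within-group variance: identical means are a non-result (p = 1);
    # separated means are a maximal result (p -> 0).
    with np.errstate(invalid="ignore"):
        t = np.where(
            degenerate, np.where(log2fc == 0, 0.0, np.sign(log2fc) * np.inf), t
        )
    p = np.where(degenerate, np.where(log2fc == 0, 1.0, 0.0), p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    max_q, min_lfc = DE_THRESHOLDS[mode]
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "q": q,
            "passed": (q < max_q) & (np.abs(log2fc) > min_lfc),
        },
        index=expr.gene_ids,
    )
    return DifferentialExpressionTable(table=table, mode=mode)


# ---------------------------------------------------------------------------
# Diffusion pseudotime
# ---------------------------------------------------------------------------


@dataclass
class PseudotimeResult:
    pseudotime: pd.Series  # per-cell, in [0, 1], root = 0
    root: str
    n_components: int


def diffusion_pseudotime(
    data: pd.DataFrame,
    n_components: int = 10,
    root: str = "auto",
    k_neighbors: int = 15,
    seed: int = 0,
    potency: pd.Series | None = None,
    n_pcs: int = 30,
) -> PseudotimeResult:
    """Diffusion pseudotime from a Gaussian-kernel kNN transition matrix.

    ``data`` is cells x features (an expression matrix transposed, or a
    precomputed embedding).  The top ``n_pcs`` principal components feed a
    kNN graph with an adaptive Gaussian kernel (bandwidth = distance to the
    k-th neighbor); the symmetrized, density-normalized kernel is
    eigendecomposed, and pseudotime is the diffusion distance to the root
    cell, rescaled to [0, 1].  ``root="auto"`` requires a ``potency``
    vector and picks its argmax.
    """
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    n = len(data)
    if n < 10:
        raise ValueError("need >= 10 cells")
    if root == "auto":
        if potency is None:
            raise ValueError('root="auto" requires a potency score per cell')
        root = str(potency.loc[data.index].idxmax())
    if root not in data.index:
        raise KeyError(f"root cell {root!r} not found")

    x = data.to_numpy(float)
    if x.shape[1] > n_pcs:
        x = PCA(n_components=n_pcs, random_state=int(seed) % (2**31)).fit_transform(x)
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(x)
    dist, idx = nn.kneighbors(x)
    sigma = dist[:, -1]
    sigma = np.where(sigma <= 0, np.median(sigma[sigma > 0]) if (sigma > 0).any() else 1.0, sigma)

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    w = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    from scipy import sparse

    kernel = sparse.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    kernel = kernel.maximum(kernel.T)
    n_comp_graph, _ = connected_components(kernel, directed=False)
    if n_comp_graph > 1:
        raise ValueError(
            f"kNN graph has {n_comp_graph} connected components; increase k_neighbors"
        )
    # Density normalization (alpha = 1) followed by symmetric normalization.
    dens = np.asarray(kernel.sum(axis=1)).ravel()
    kdense = kernel.toarray() / np.outer(dens, dens)
    d = kdense.sum(axis=1)
    sym = kdense / np.sqrt(np.outer(d, d))
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # Markov eigenvectors: psi = phi / sqrt(d), skipping the trivial first.
    psi = evecs / np.sqrt(d)[:, None]
    n_use = min(n_components, n - 1)
    lam = evals[1 : n_use + 1]
    lam = np.clip(lam, None, 1 - 1e-12)
    comps = psi[:, 1 : n_use + 1] * (lam / (1 - lam))[None, :]

    root_idx = int(data.index.get_loc(root))
    dpt = np.sqrt(((comps - comps[root_idx]) ** 2).sum(axis=1))
    if dpt.max() > 0:
        dpt = dpt / dpt.max()
    return PseudotimeResult(
        pseudotime=pd.Series(dpt, index=data.index, name="pseudotime"),
        root=str(root),
        n_components=n_use,
    )


# ---------------------------------------------------------------------------
# Trend tests
# ---------------------------------------------------------------------------


@dataclass
class TrendTable:
    table: pd.DataFrame  # per gene: rho, p, q, direction


def trend_test(expr: ExpressionMatrix, pseudotime: PseudotimeResult | pd.Series) -> TrendTable:
    """Spearman correlation of each gene (or pathway-score row) with
    pseudotime; BH adjustment over non-constant rows, constant rows NA."""
    pt = pseudotime.pseudotime if isinstance(pseudotime, PseudotimeResult) else pseudotime
    cells = [c for c in expr.sample_ids if c in pt.index]
    if len(cells) < 10:
        raise ValueError("need >= 10 cells with pseudotime")
    sub = expr.values[cells]
    ptv = pt.loc[cells].to_numpy(float)
    rho = np.full(len(sub), np.nan)
    pvals = np.full(len(sub), np.nan)
    for i, (_, row) in enumerate(sub.iterrows()):
        vals = row.to_numpy(float)
        if np.all(vals == vals[0]):
            continue
        r, p = stats.spearmanr(vals, ptv)
        rho[i], pvals[i] = r, p
    q = np.full(len(sub), np.nan)
    tested = np.isfinite(pvals)
    if tested.any():
        _, q[tested], _, _ = multipletests(pvals[tested], method="fdr_bh")
    direction = np.where(~np.isfinite(rho), "na", np.where(rho > 0, "up", "down"))
    table = pd.DataFrame(
        {"rho": rho, "p": pvals, "q": q, "direction": direction}, index=sub.index
    )
    return TrendTable(table=table)


# ---------------------------------------------------------------------------
# Evidence intersection
# ---------------------------------------------------------------------------


@dataclass
class CandidateEvidenceTable:
    table: pd.DataFrame  # per gene: four membership flags, evidence_count, core

    @property
    def core(self) -> list[str]:
        return list(self.table.index[self.table["core"]])


def intersect_candidates(
    module_genes: Iterable[str],
    sc_de_genes: Iterable[str],
    up_cohort1: Iterable[str],
    up_cohort2: Iterable[str],
    catalog: Iterable[str] | None = None,
) -> CandidateEvidenceTable:
    """Four-way evidence intersection over a shared gene namespace.

    The table covers the union of the four evidence sets (optionally
    restricted to ``catalog``, e.g. a deubiquitinase gene list); the core
    candidates are exactly the genes present in all four sets.  Rows are
    ordered by decreasing evidence count, then gene id.
    """
    sets = {
        "in_module": set(module_genes),
        "in_sc_de": set(sc_de_genes),
        "up_cohort1": set(up_cohort1),
        "up_cohort2": set(up_cohort2),
    }
    universe = set().union(*sets.values())
    if catalog is not None:
        universe &= set(catalog)
    rows = []
    for g in sorted(universe):
        flags = {k: g in v for k, v in sets.items()}
        count = sum(flags.values())
        rows.append({"gene": g, **flags, "evidence_count": count, "core": count == 4})
    table = (
        pd.DataFrame(rows).set_index("gene")
        if rows
        else pd.DataFrame(
            columns=["in_module", "in_sc_de", "up_cohort1", "up_cohort2", "evidence_count", "core"]
        )
    )
    if len(table):
        # Rows were built in gene-id order; a stable sort on evidence count
        # yields (count desc, gene id asc).
        table = table.sort_values("evidence_count", ascending=False, kind="stable")
    return CandidateEvidenceTable(table=table)
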