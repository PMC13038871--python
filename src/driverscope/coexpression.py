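"""Weighted co-expression module detection.

Unsigned weighted network analysis: soft-threshold power chosen by the
scale-free topology criterion, topological overlap similarity,
average-linkage hierarchical modules with a static tree cut, eigengene
merging, and module-trait statistics (kME / GS).

Expression is oriented samples x genes throughout this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "SoftThresholdReport",
    "ModuleSet",
    "ModuleTraitStats",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_trait_stats",
]

GREY = "grey"


@dataclass
class SoftThresholdReport:
    table: pd.DataFrame  # per power: r_squared (signed), mean_connectivity
    chosen_power: int
    reached_target: bool
    target_r2: float = 0.85


def _check_no_constant(expr: pd.DataFrame) -> None:
    variances = expr.var(axis=0, ddof=0)
    if (variances == 0).any():
        name = variances.index[int(np.argmax(variances.to_numpy() == 0))]
        raise ValueError(f"constant gene {name!r}")


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 p(k) vs log10 k fit over occupied bins.

    Falls back to fewer bins when fewer than 5 of ``n_bins`` are occupied.
    Sign follows -slope: a scale-free (decreasing) degree distribution
    yields a positive value.
    """
    k = connectivity[connectivity > 0]
    if len(k) < 5:
        return 0.0
    for bins in (n_bins, 8, 6, 5):
        edges = np.linspace(k.min(), k.max() + 1e-12, bins + 1)
        which = np.digitize(k, edges[1:-1])
        centers, freqs = [], []
        for b in range(bins):
            sel = which == b
            if sel.sum() > 0:
                centers.append(k[sel].mean())
                freqs.append(sel.sum() / len(k))
        if len(centers) >= 5:
            break
    if len(centers) < 3:
        return 0.0
    lx, ly = np.log10(centers), np.log10(freqs)
    slope, _, r, _, _ = stats.linregress(lx, ly)
    return float(-np.sign(slope) * r**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 21)),
    target_r2: float = 0.85,
) -> SoftThresholdReport:
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate power the unsigned adjacency |cor|^beta gives
    per-gene connectivity; the chosen beta is the smallest whose signed
    scale-free fit reaches ``target_r2``, else the argmax with a warning.
    """
    if expr.shape[1] < 20 or expr.shape[0] < 10:
        raise ValueError("need >= 20 genes and >= 10 samples")
    _check_no_constant(expr)
    cor = np.corrcoef(expr.to_numpy(float), rowvar=False)
    np.fill_diagonal(cor, 0.0)
    acor = np.abs(cor)
    rows = []
    for beta in powers:
        adj = acor**beta
        k = adj.sum(axis=1)
        rows.append((int(beta), _scale_free_r2(k), float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "r_squared", "mean_connectivity"]).set_index("power")
    hits = table.index[table["r_squared"] >= target_r2]
    if len(hits):
        chosen, reached = int(hits[0]), True
    else:
        chosen, reached = int(table["r_squared"].idxmax()), False
        logger.warning(
            "no power reached scale-free R^2 >= %.2f; falling back to argmax (%d)",
            target_r2, chosen,
        )
    return SoftThresholdReport(
        table=table, chosen_power=chosen, reached_target=reached, target_r2=target_r2
    )


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of an unsigned adjacency matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L = A @ A (shared-neighbor weight); diagonal set to 1.
    """
    a = np.asarray(adjacency, dtype=float)
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class ModuleSet:
    labels: pd.Series  # per-gene module label; unassigned = "grey"
    eigengenes: pd.DataFrame  # samples x modules
    min_module_size: int
    merge_cut_height: float


def _eigengene(expr: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """First principal component of standardized member expression,
    sign-oriented so that the mean member correlation is positive."""
    x = expr[list(genes)].to_numpy(float)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pc = u[:, 0] * s[0]
    cors = np.array([np.corrcoef(pc, z[:, j])[0, 1] for j in range(z.shape[1])])
    if cors.mean() < 0:
        pc = -pc
    return pd.Series(pc, index=expr.index)


def detect_modules(
    expr: pd.DataFrame,
    beta: int,
    min_module_size: int = 30,
    merge_cut_height: float = 0.25,
    cut_height: float = 0.99,
) -> ModuleSet:
    """TOM-based hierarchical modules with eigengene merging.

    Average-linkage clustering of TOM dissimilarity is cut statically at
    ``cut_height``; branches below ``min_module_size`` go to "grey";
    module pairs whose eigengenes correlate above 1 - ``merge_cut_height``
    are merged iteratively.  Modules are named M1, M2, ... by decreasing
    size.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    genes = expr.columns
    if len(genes) < min_module_size:
        logger.warning("fewer genes than min_module_size; everything is grey")
        return ModuleSet(
            labels=pd.Series(GREY, index=genes, name="module"),
            eigengenes=pd.DataFrame(index=expr.index),
            min_module_size=min_module_size,
            merge_cut_height=merge_cut_height,
        )
    _check_no_constant(expr)
    cor = np.corrcoef(expr.to_numpy(float), rowvar=False)
    adj = np.abs(cor) ** beta
    tom = tom_similarity(adj)
    diss = 1.0 - tom
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    labels = pd.Series(GREY, index=genes, name="module", dtype=object)
    sizes = pd.Series(raw).value_counts()
    keep = [cl for cl in sizes.index if sizes[cl] >= min_module_size]
    groups = {cl: genes[raw == cl] for cl in keep}

    # Iterative eigengene merging.
    while True:
        if len(groups) < 2:
            break
        eig = {cl: _eigengene(expr, g) for cl, g in groups.items()}
        names = list(groups)
        best_pair, best_cor = None, -np.inf
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                c = float(np.corrcoef(eig[names[i]], eig[names[j]])[0, 1])
                if c > best_cor:
                    best_cor, best_pair = c, (names[i], names[j])
        if best_cor <= 1.0 - merge_cut_height:
            break
        a, b = best_pair
        groups[a] = groups[a].append(groups[b])
        del groups[b]

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), str(kv[0])))
    eigengenes = {}
    for rank, (cl, g) in enumerate(ordered, start=1):
        name = f"M{rank}"
        labels.loc[g] = name
        eigengenes[name] = _eigengene(expr, g)
    return ModuleSet(
        labels=labels,
        eigengenes=pd.DataFrame(eigengenes, index=expr.index),
        min_module_size=min_module_size,
        merge_cut_height=merge_cut_height,
    )


@dataclass
class ModuleTraitStats:
    module_trait_cor: pd.DataFrame  # modules x traits
    module_trait_p: pd.DataFrame
    kme: pd.Series  # per-gene correlation with own module eigengene
    gs: pd.DataFrame  # genes x traits


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def module_trait_stats(
    modules: ModuleSet,
    expr: pd.DataFrame,
    traits: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> ModuleTraitStats:
    """Pearson module-trait correlations plus per-gene kME and GS.

    Constant traits are reported as NA.  kME is each gene's correlation
    with its own module's eigengene (NA for grey genes); GS is each gene's
    correlation with each trait.
    """
    traits = pd.DataFrame(traits, index=expr.index)
    if not traits.index.equals(expr.index):
        raise ValueError("traits not aligned to samples")
    eig = modules.eigengenes
    cor = pd.DataFrame(index=eig.columns, columns=traits.columns, dtype=float)
    pval = cor.copy()
    for t in traits.columns:
        tv = traits[t].to_numpy(float)
        if np.std(tv) == 0:
            continue  # stays NA
        for m in eig.columns:
            r, p = _pearson_with_p(eig[m].to_numpy(), tv)
            cor.at[m, t], pval.at[m, t] = r, p

    kme = pd.Series(np.nan, index=expr.columns, name="kme")
    for m in eig.columns:
        members = modules.labels.index[modules.labels == m]
        ev = eig[m].to_numpy()
        for g in members:
            kme.at[g] = np.corrcoef(expr[g].to_numpy(float), ev)[0, 1]

    gs = pd.DataFrame(index=expr.columns, columns=traits.columns, dtype=float)
    for t in traits.columns:
        tv = traits[t].to_numpy(float)
        if np.std(tv) == 0:
            continue
        x = expr.to_numpy(float)
        xz = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
        tz = (tv - tv.mean()) / tv.std()
        gs[t] = xz.T @ tz / len(tv)
    return ModuleTraitStats(module_trait_cor=cor, module_trait_p=pval, kme=kme, gs=gs)
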