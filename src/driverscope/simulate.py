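"""Synthetic cohorts with planted, recoverable ground truth.

Three generators emulate the statistical structure the downstream analyses
assume:

* :func:`simulate_bulk_cohort` — log-normal-ish bulk expression driven by
  latent pathway activities, with survival times from an exponential
  proportional-hazards model whose linear predictor is a weighted sum of
  planted pathway activities.
* :func:`simulate_sc_dataset` — negative-binomial single-cell counts with
  cell-type mean profiles, contiguous CNV gain/loss blocks in the malignant
  type, planted differentially expressed genes, a pseudotime axis with
  trend genes, and sender/receiver ligand-receptor structure.
* :func:`simulate_promoters` — uniform-background promoter sequences with
  motif instances planted at recorded positions.

Every generator is a pure function of its config (seed included) and
returns a :class:`GroundTruth` record of everything planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GenomeAnnotation,
    PositionWeightMatrix,
    SurvivalTable,
)

__all__ = [
    "BulkSimConfig",
    "ScSimConfig",
    "GroundTruth",
    "simulate_bulk_cohort",
    "simulate_sc_dataset",
    "simulate_promoters",
]


@dataclass
class GroundTruth:
    """JSON-serializable record of every planted element of a simulation."""

    kind: str
    planted: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"kind": self.kind, "planted": self.planted}, indent=2, sort_keys=True
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        text = source.read_text() if isinstance(source, Path) else str(source)
        obj = json.loads(text)
        return cls(kind=obj["kind"], planted=obj["planted"])


# ---------------------------------------------------------------------------
# Bulk cohort
# ---------------------------------------------------------------------------


@dataclass
class BulkSimConfig:
    """Configuration for a bulk expression + survival cohort.

    ``planted_pathways`` maps pathway index to the log hazard ratio per unit
    of latent pathway activity (effect size theta).  ``baseline_hazard`` is
    the exponential event rate per day; the default gives a median survival
    of about a year at the baseline linear predictor, in line with an
    aggressive carcinoma cohort.  ``noise_sd`` is the per-gene residual
    standard deviation on the log2 scale.
    """

    n_samples: int = 200
    n_genes: int = 2000
    n_pathways: int = 20
    genes_per_pathway: int = 20
    planted_pathways: dict[int, float] = field(default_factory=dict)
    baseline_hazard: float = np.log(2) / 365.0
    censoring_rate: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_pathways, self.genes_per_pathway) < 1:
            raise ValueError("counts must be positive")
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError("pathway memberships exceed gene count")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        for idx, theta in self.planted_pathways.items():
            if not 0 <= int(idx) < self.n_pathways:
                raise ValueError(f"planted pathway index {idx} out of range")
            if not np.isfinite(theta):
                raise ValueError("effect sizes must be finite")


def simulate_bulk_cohort(
    config: BulkSimConfig,
) -> tuple[ExpressionMatrix, SurvivalTable, GeneSetCollection, GroundTruth]:
    """Simulate a bulk cohort with pathway-linked proportional hazards.

    Each pathway p has a latent activity ``a_p ~ N(0, 1)`` per sample; its
    member genes express ``a_p`` plus N(0, noise_sd^2) noise on the log2
    scale (non-member genes are pure noise).  Event times are exponential
    with hazard ``baseline_hazard * exp(sum_p theta_p * a_p)``; censoring is
    independent exponential with rate calibrated so that the expected
    censored fraction at the baseline linear predictor equals
    ``censoring_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, N, P, M = (
        config.n_genes,
        config.n_samples,
        config.n_pathways,
        config.genes_per_pathway,
    )
    gene_ids = [f"G{i:05d}" for i in range(G)]
    sample_ids = [f"S{i:04d}" for i in range(N)]
    pathway_names = [f"PW{p:03d}" for p in range(P)]

    activity = rng.standard_normal((P, N))  # latent pathway activity
    expr = rng.normal(0.0, config.noise_sd, size=(G, N))
    membership: dict[str, list[str]] = {}
    for p in range(P):
        rows = slice(p * M, (p + 1) * M)
        expr[rows, :] += activity[p]
        membership[pathway_names[p]] = gene_ids[p * M : (p + 1) * M]

    eta = np.zeros(N)
    for idx, theta in config.planted_pathways.items():
        eta += float(theta) * activity[int(idx)]
    hazard = config.baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        cens_rate = config.baseline_hazard * config.censoring_rate / (
            1.0 - config.censoring_rate
        )
        cens_time = rng.exponential(1.0 / cens_rate, size=N)
    else:
        cens_time = np.full(N, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    time = np.maximum(time, 1e-6)  # strictly positive follow-up

    surv = SurvivalTable(
        pd.DataFrame({"time": time, "event": event}, index=pd.Index(sample_ids, name="subject_id"))
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=gene_ids, columns=sample_ids), mode="continuous"
    )
    sets = GeneSetCollection(
        {
            name: GeneSet(name, "simulated pathway", tuple(genes))
            for name, genes in membership.items()
        }
    )
    truth = GroundTruth(
        kind="bulk",
        planted={
            "prognostic_pathways": {
                pathway_names[int(i)]: float(t)
                for i, t in sorted(config.planted_pathways.items())
            },
            "latent_activity": {
                pathway_names[int(i)]: activity[int(i)].tolist()
                for i in sorted(config.planted_pathways)
            },
            "observed_censoring_fraction": float(1 - event.mean()),
            "n_samples": N,
            "n_pathways": P,
        },
    )
    return matrix, surv, sets, truth


# ---------------------------------------------------------------------------
# Single-cell dataset
# ---------------------------------------------------------------------------


@dataclass
class ScSimConfig:
    """Configuration for a negative-binomial single-cell dataset.

    ``cell_types`` maps type name to cell count; ``reference_types`` are the
    non-malignant populations used as the CNV reference; ``malignant_type``
    is the tumor population carrying the planted CNV blocks, DE shifts and
    pseudotime axis.  ``cnv_blocks`` are (start_gene_index, end_gene_index,
    fold_change) triples over the genomic gene order, half-open.
    ``dispersion`` is the negative-binomial size parameter (smaller = more
    overdispersed), a typical droplet-data value by default.
    """

    cell_types: dict[str, int] = field(
        default_factory=lambda: {"Malignant": 300, "Immune": 300, "Stromal": 200}
    )
    reference_types: tuple[str, ...] = ("Immune", "Stromal")
    malignant_type: str = "Malignant"
    n_genes: int = 1000
    n_chromosomes: int = 5
    cnv_blocks: Sequence[tuple[int, int, float]] = ()
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> log2FC
    pseudotime_genes: dict[str, str] = field(default_factory=dict)  # gene -> trend
    lr_pairs: Sequence[tuple[str, str, str, str, float]] = ()
    dispersion: float = 2.0
    mean_library_size: float = 5000.0
    seed: int = 0

    def validate(self) -> None:
        if not self.cell_types:
            raise ValueError("cell_types is empty")
        for name, n in self.cell_types.items():
            if n < 1:
                raise ValueError(f"cell type {name!r} has no cells")
        if self.malignant_type not in self.cell_types:
            raise ValueError(f"malignant type {self.malignant_type!r} unknown")
        if self.malignant_type in self.reference_types:
            raise ValueError("malignant type cannot be a reference type")
        for t in self.reference_types:
            if t not in self.cell_types:
                raise ValueError(f"reference type {t!r} unknown")
        for start, end, f in self.cnv_blocks:
            if not (0 <= start < end <= self.n_genes):
                raise ValueError(f"CNV block [{start}, {end}) out of range")
            if f <= 0:
                raise ValueError("CNV fold changes must be > 0")
        for trend in self.pseudotime_genes.values():
            if trend not in ("late-up", "early-peak", "down"):
                raise ValueError(f"unknown pseudotime trend {trend!r}")


def _gene_index(gene: str) -> int:
    return int(gene.lstrip("G"))


def _trend_multiplier(trend: str, u: np.ndarray, amplitude: float = 3.0) -> np.ndarray:
    """Mean fold change (log2 amplitude) as a function of pseudotime u."""
    if trend == "late-up":
        shape = 1.0 / (1.0 + np.exp(-(u - 0.6) / 0.08))
    elif trend == "down":
        shape = 1.0 - 1.0 / (1.0 + np.exp(-(u - 0.4) / 0.08))
    elif trend == "early-peak":
        shape = np.exp(-((u - 0.25) ** 2) / (2 * 0.15**2))
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(trend)
    return 2.0 ** (amplitude * shape)


def simulate_sc_dataset(
    config: ScSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GenomeAnnotation, GroundTruth]:
    """Simulate single-cell counts with planted CNV, DE, trend and LR structure.

    Returns the counts matrix (genes x cells), a per-cell metadata frame
    (``cell_type``, ``is_reference``, ``is_malignant``, ``pseudotime``), a
    genomically ordered gene annotation, and the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(G)]

    # Genomic layout: genes split evenly across chromosomes, 2 kb apart.
    per_chrom = int(np.ceil(G / config.n_chromosomes))
    chroms, starts = [], []
    for i in range(G):
        c = i // per_chrom
        chroms.append(f"chr{c + 1}")
        starts.append((i % per_chrom) * 2000)
    annotation = GenomeAnnotation(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chrom": chroms,
                "start": starts,
                "end": [s + 1000 for s in starts],
                "strand": ["+"] * G,
            }
        )
    )

    # Base mean profile shared across types; each type up-regulates its own
    # marker block so clustering has signal to find.
    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    base_mean /= base_mean.sum()
    type_names = list(config.cell_types)
    marker_block = max(10, G // 50)
    type_factors = {}
    for t_idx, t in enumerate(type_names):
        f = np.ones(G)
        lo = (t_idx * marker_block * 3) % max(1, G - marker_block)
        f[lo : lo + marker_block] *= 8.0
        type_factors[t] = f

    cells, cell_types_col = [], []
    for t in type_names:
        n = config.cell_types[t]
        cells.extend(f"{t}_{i:04d}" for i in range(n))
        cell_types_col.extend([t] * n)
    n_cells = len(cells)
    cell_types_arr = np.array(cell_types_col)
    is_malignant = cell_types_arr == config.malignant_type
    is_reference = np.isin(cell_types_arr, config.reference_types)

    # Per-cell baseline mean matrix (genes x cells); the library size is
    # tied to the baseline so that planted multiplicative effects change
    # expected counts by exactly their stated fold (a gained block really
    # carries more transcript mass, as in a genuine copy-number gain).
    mean = np.empty((G, n_cells))
    for t in type_names:
        cols = cell_types_arr == t
        mean[:, cols] = (base_mean * type_factors[t])[:, None]
    lib = rng.lognormal(
        mean=np.log(config.mean_library_size), sigma=0.2, size=n_cells
    )
    mu = mean / mean.sum(axis=0, keepdims=True) * lib[None, :]

    for start, end, f in config.cnv_blocks:
        mu[start:end, :][:, is_malignant] *= f
    for gene, lfc in config.de_genes.items():
        mu[_gene_index(gene), is_malignant] *= 2.0 ** float(lfc)

    pseudotime = np.full(n_cells, np.nan)
    u = rng.uniform(0.0, 1.0, size=int(is_malignant.sum()))
    pseudotime[is_malignant] = u
    for gene, trend in config.pseudotime_genes.items():
        mu[_gene_index(gene), is_malignant] *= _trend_multiplier(trend, u)

    for ligand, receptor, sender, receiver, strength in config.lr_pairs:
        mu[_gene_index(ligand), cell_types_arr == sender] *= float(strength)
        mu[_gene_index(receptor), cell_types_arr == receiver] *= float(strength)
    # Negative binomial with size r: p = r / (r + mu).
    r = config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=cells), mode="counts"
    )
    metadata = pd.DataFrame(
        {
            "cell_type": cell_types_arr,
            "is_reference": is_reference,
            "is_malignant": is_malignant,
            "pseudotime": pseudotime,
        },
        index=pd.Index(cells, name="cell_id"),
    )
    truth = GroundTruth(
        kind="single_cell",
        planted={
            "cnv_blocks": [
                {
                    "start": int(s),
                    "end": int(e),
                    "fold_change": float(f),
                    "genes": gene_ids[s:e],
                }
                for s, e, f in config.cnv_blocks
            ],
            "de_genes": {g: float(v) for g, v in config.de_genes.items()},
            "pseudotime_genes": dict(config.pseudotime_genes),
            "lr_pairs": [
                {
                    "ligand": l, "receptor": rcp, "sender": snd,
                    "receiver": rcv, "strength": float(st),
                }
                for l, rcp, snd, rcv, st in config.lr_pairs
            ],
            "malignant_cells": [c for c, m in zip(cells, is_malignant) if m],
            "reference_cells": [c for c, m in zip(cells, is_reference) if m],
        },
    )
    return matrix, metadata, annotation, truth


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------


def simulate_promoters(
    n_sequences: int,
    length: int,
    motif: PositionWeightMatrix,
    planted_fraction: float,
    seed: int = 0,
) -> tuple[dict[str, str], GroundTruth]:
    """Uniform-background promoter sequences with planted motif instances.

    The first ``round(planted_fraction * n_sequences)`` sequences receive one
    motif instance sampled column-wise from the PWM, at a position recorded
    in the ground truth.
    """
    if length < motif.width:
        raise ValueError(
            f"sequence length {length} shorter than motif width {motif.width}"
        )
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    n_planted = int(round(planted_fraction * n_sequences))
    seqs: dict[str, str] = {}
    plants: list[dict] = []
    for i in range(n_sequences):
        name = f"prom{i:04d}"
        bases = alphabet[rng.integers(0, 4, size=length)]
        if i < n_planted:
            pos = int(rng.integers(0, length - motif.width + 1))
            inst = [
                alphabet[rng.choice(4, p=motif.probs[:, j])]
                for j in range(motif.width)
            ]
            bases[pos : pos + motif.width] = inst
            plants.append(
                {"sequence": name, "position": pos, "instance": "".join(inst)}
            )
        seqs[name] = "".join(bases)
    truth = GroundTruth(
        kind="promoters",
        planted={
            "motif_id": motif.motif_id,
            "motif_width": motif.width,
            "occurrences": plants,
        },
    )
    return seqs, truth
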