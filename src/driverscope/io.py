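"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
* Genomic coordinates are 0-based half-open everywhere; BED-like input is
  taken as already 0-based half-open.
* Gene identifiers are matched case-sensitively with no alias resolution.
* All writers emit the same dialects the readers accept, so every format
  round-trips.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "ExpressionMatrix",
    "SurvivalTable",
    "PositionWeightMatrix",
    "GenomeAnnotation",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
    "read_survival",
    "write_survival",
    "read_pwm",
    "write_pwm",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
]

PWM_ALPHABET = ("A", "C", "G", "T")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        if any(not g or g != g.strip() for g in self.genes):
            raise FormatError(f"gene set {self.name!r} contains blank gene ids")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (GMT semantics)."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise FormatError(f"key {name!r} does not match set name {gs.name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})


@dataclass
class ExpressionMatrix:
    """Genes x samples (or cells) expression values with named axes.

    ``mode`` declares the scale: ``"continuous"`` for log-normalized
    expression, ``"counts"`` for raw non-negative integer counts.
    """

    values: pd.DataFrame
    mode: str = "continuous"

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "counts"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise FormatError("expression matrix contains non-finite values")
        if self.mode == "counts":
            if (arr < 0).any():
                raise FormatError("counts matrix contains negative values")
            if not np.array_equal(arr, np.round(arr)):
                raise FormatError("counts matrix contains non-integer values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def align_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.sample_ids)
        if missing:
            raise KeyError(f"samples absent from matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values[ids], mode=self.mode)


@dataclass
class SurvivalTable:
    """Per-subject follow-up time (days), event indicator and covariates.

    ``data`` is indexed by subject id with columns ``time``, ``event`` and
    any number of covariate columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise FormatError(f"survival table lacks column {col!r}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate subject ids")
        t = self.data["time"].to_numpy(float)
        if not np.all(np.isfinite(t)) or (t <= 0).any():
            raise FormatError("follow-up times must be finite and strictly positive")
        e = self.data["event"].to_numpy()
        if not np.isin(e, [0, 1]).all():
            raise FormatError("event indicator must be 0 or 1")
        self.data = self.data.assign(
            time=t, event=self.data["event"].astype(int)
        )

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def __len__(self) -> int:
        return len(self.data)

    def loc(self, subject_ids: Iterable[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(subject_ids)].copy())


@dataclass(frozen=True)
class PositionWeightMatrix:
    """A probability PWM over the DNA alphabet A, C, G, T."""

    motif_id: str
    probs: np.ndarray  # 4 x width

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise FormatError(
                f"PWM {self.motif_id!r} must have 4 rows (A,C,G,T), got shape {probs.shape}"
            )
        if probs.shape[1] < 1:
            raise FormatError(f"PWM {self.motif_id!r} has zero width")
        if (probs < 0).any():
            raise FormatError(f"PWM {self.motif_id!r} has negative entries")
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise FormatError(f"PWM {self.motif_id!r} columns do not sum to 1")
        object.__setattr__(self, "probs", probs)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(PWM_ALPHABET[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(self.motif_id, self.probs[::-1, ::-1])


@dataclass
class GenomeAnnotation:
    """Gene coordinates (0-based half-open) with strand."""

    records: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        req = ["gene_id", "chrom", "start", "end", "strand"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise FormatError(f"annotation lacks columns {missing}")
        df = self.records[req].copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
            raise FormatError(f"gene {bad!r} has start >= end")
        if not df["strand"].isin(["+", "-"]).all():
            raise FormatError("strand must be '+' or '-'")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene id {dup!r} in annotation")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def genomic_order(self) -> pd.DataFrame:
        """Records sorted by (chrom, start); stable within ties."""
        return self.records.sort_values(
            ["chrom", "start", "end", "gene_id"], kind="stable"
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated line per set, name / description /
    genes. Duplicate genes within a line are dropped with a warning."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning(
                        "%s: line %d: duplicate gene %r in set %r dropped",
                        path, lineno, g, name,
                    )
                seen.setdefault(g)
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, desc, tuple(seen))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_matrix(
    path: str | Path, format: str = "tsv", mode: str = "continuous"
) -> ExpressionMatrix:
    """Read a genes x samples matrix.

    ``format="tsv"``: tab- (or comma-) separated with a header row of sample
    ids and gene ids in the first column.  ``format="mtx"``: MatrixMarket
    coordinate file with companion ``<stem>.rows.txt`` / ``<stem>.cols.txt``
    name files (one id per line).
    """
    path = Path(path)
    if format == "tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0).astype(float)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx":
        stem = path.with_suffix("")
        rows_path = stem.with_suffix(".rows.txt")
        cols_path = stem.with_suffix(".cols.txt")
        for p in (rows_path, cols_path):
            if not p.exists():
                raise FormatError(f"companion name file missing: {p}")
        mat = scipy.io.mmread(path)
        genes = rows_path.read_text().splitlines()
        samples = cols_path.read_text().splitlines()
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if dense.shape != (len(genes), len(samples)):
            raise FormatError(
                f"{path}: matrix shape {dense.shape} does not match name files "
                f"({len(genes)} x {len(samples)})"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    return ExpressionMatrix(df, mode=mode)


def write_matrix(
    matrix: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        matrix.values.to_csv(path, sep="\t", float_format="%.10g")
    elif format == "mtx":
        stem = path.with_suffix("")
        sparse = scipy.sparse.coo_matrix(matrix.values.to_numpy())
        scipy.io.mmwrite(str(path), sparse)
        stem.with_suffix(".rows.txt").write_text(
            "\n".join(matrix.gene_ids) + "\n"
        )
        stem.with_suffix(".cols.txt").write_text(
            "\n".join(matrix.sample_ids) + "\n"
        )
    else:
        raise ValueError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# Survival tables
# ---------------------------------------------------------------------------


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a survival TSV/CSV with columns id (or first column), time,
    event; any extra columns are retained as covariates."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    id_col = df.columns[0]
    for col in ("time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    df.index.name = "subject_id"
    return SurvivalTable(df)


def write_survival(surv: SurvivalTable, path: str | Path) -> None:
    out = surv.data.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# PWMs (JASPAR-style)
# ---------------------------------------------------------------------------

_JASPAR_ROW = re.compile(r"^([ACGT])\s*\[?\s*([-\d.eE+\s]*?)\s*\]?\s*$")


def read_pwm(path: str | Path, pseudocount: float = 0.5) -> list[PositionWeightMatrix]:
    """Parse JASPAR-style motif blocks.

    A block is a ``>`` header line followed by four rows (A, C, G, T) of
    whitespace-separated numbers, optionally bracketed.  Count matrices get
    ``pseudocount`` added to every cell before column normalization;
    matrices whose columns already sum to 1 are taken as probabilities and
    returned unchanged.
    """
    pwms: list[PositionWeightMatrix] = []
    motif_id: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal motif_id, rows
        if motif_id is None:
            return
        if len(rows) != 4:
            raise FormatError(
                f"motif {motif_id!r}: expected 4 rows (A,C,G,T), got {len(rows)}"
            )
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise FormatError(f"motif {motif_id!r}: unequal row lengths {lengths}")
        mat = np.array([rows[b] for b in PWM_ALPHABET], dtype=float)
        colsums = mat.sum(axis=0)
        if np.allclose(colsums, 1.0, atol=1e-6):
            probs = mat
        else:
            mat = mat + pseudocount
            probs = mat / mat.sum(axis=0, keepdims=True)
        pwms.append(PositionWeightMatrix(motif_id, probs))
        motif_id, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                continue
            m = _JASPAR_ROW.match(line)
            if m is None:
                raise FormatError(f"{path}: unparseable motif row: {line!r}")
            base, values = m.group(1), m.group(2).split()
            if motif_id is None:
                raise FormatError(f"{path}: motif row before any '>' header")
            if base in rows:
                raise FormatError(f"motif {motif_id!r}: duplicate row for {base}")
            rows[base] = [float(v) for v in values]
    flush()
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def write_pwm(pwms: Iterable[PositionWeightMatrix], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for i, base in enumerate(PWM_ALPHABET):
                vals = " ".join(f"{v:.10g}" for v in pwm.probs[i])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# BED-like annotation
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Read a 6-column BED-like file: chrom, start, end, gene_id, score,
    strand.  Coordinates are 0-based half-open."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    return GenomeAnnotation(
        df[["gene_id", "chrom", "start", "end", "strand"]]
    )


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    df = annotation.records
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "gene_id": df["gene_id"],
            "score": 0,
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: uppercase sequence} mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
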