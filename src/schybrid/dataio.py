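"""Validated in-memory containers and on-disk readers/writers.

The pipeline exchanges four kinds of artifact:

* expression matrices (cells x genes, Matrix Market + id files, or dense CSV),
* per-cell annotation tables (cell id, reference label, condition group),
* gene-set collections (GMT), and
* per-cell class-probability tables (CSV) — the central interchange object,
  whether produced by the built-in classifier or imported from an external
  annotator such as TOSICA or Capybara.

Cells are rows everywhere. All indices are 0-based in memory; Matrix Market
files stay 1-based on disk per the standard.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from ._utils import atomic_write_bytes, atomic_write_text, write_manifest

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
LOGNORM = "lognorm"
_LAYERS = (RAW_COUNTS, LOGNORM)

#: row sums of an imported probability table may deviate this much from 1
#: before the row is rejected; smaller deviations are renormalized away.
PROB_ROW_SUM_TOL = 1e-3
#: tolerance on the simplex invariant enforced by :class:`ProbMatrix`.
PROB_SIMPLEX_TOL = 1e-6


class DataValidationError(ValueError):
    """An on-disk artifact or in-memory container violated its contract."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise DataValidationError(f"{what} are not unique")


@dataclass
class ExpressionMatrix:
    """A cells x genes matrix of counts or log-normalized expression."""

    values: np.ndarray | sparse.spmatrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    layer_tag: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.layer_tag not in _LAYERS:
            raise DataValidationError(f"unknown layer_tag {self.layer_tag!r}")
        n, g = self.values.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise DataValidationError(
                f"matrix is {n} cells x {g} genes but {len(self.cell_ids)} "
                f"cell ids and {len(self.gene_ids)} gene ids were given"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        data = self.values.data if sparse.issparse(self.values) else self.values
        if data.size and np.min(data) < 0:
            raise DataValidationError("expression matrix contains negative entries")
        if data.size and not np.all(np.isfinite(data)):
            raise DataValidationError("expression matrix contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        vals = self.values[mask]
        return ExpressionMatrix(vals, self.cell_ids[mask], self.gene_ids, self.layer_tag)


@dataclass
class CellTable:
    """Per-cell annotation: id, reference label, condition group.

    ``vocabulary`` is the declared label set; by default the labels observed.
    """

    df: pd.DataFrame
    vocabulary: tuple[str, ...] = ()

    REQUIRED = ("cell_id", "reference_label", "group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise DataValidationError(f"cell table is missing columns {missing}")
        self.df = self.df.reset_index(drop=True)
        _check_unique(self.df["cell_id"].to_numpy(object), "cell ids")
        if not self.vocabulary:
            self.vocabulary = tuple(sorted(self.df["reference_label"].unique()))
        unknown = set(self.df["reference_label"]) - set(self.vocabulary)
        if unknown:
            raise DataValidationError(
                f"reference labels {sorted(unknown)} outside declared vocabulary"
            )

    @property
    def cell_ids(self) -> np.ndarray:
        return self.df["cell_id"].to_numpy(object)

    def labels_for(self, cell_ids: np.ndarray) -> np.ndarray:
        mapping = dict(zip(self.df["cell_id"], self.df["reference_label"]))
        try:
            return np.array([mapping[c] for c in cell_ids], dtype=object)
        except KeyError as exc:  # pragma: no cover - message clarity
            raise DataValidationError(f"cell {exc.args[0]!r} has no annotation") from exc

    def groups_for(self, cell_ids: np.ndarray) -> np.ndarray:
        mapping = dict(zip(self.df["cell_id"], self.df["group"]))
        return np.array([mapping[c] for c in cell_ids], dtype=object)


@dataclass
class GeneSetCollection:
    """Named gene lists (GMT); used both as classifier features and knockouts."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise DataValidationError(f"gene set {name!r} is empty")

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def match(self, name: str, gene_ids: np.ndarray,
              case_insensitive: bool = False) -> tuple[list[str], list[str]]:
        """Split a set into members present/absent in ``gene_ids``.

        Matching is case-sensitive exact by default; the fallback folds case
        (mouse vs human symbol conventions differ, and silent folding can
        create false joins, so it is opt-in).
        """
        members = self.sets[name]
        if case_insensitive:
            lookup = {str(g).lower(): g for g in gene_ids}
            hit = [lookup[m.lower()] for m in members if m.lower() in lookup]
            hitset = {m.lower() for m in members if m.lower() in lookup}
            missing = [m for m in members if m.lower() not in hitset]
        else:
            present = set(map(str, gene_ids))
            hit = [m for m in members if m in present]
            missing = [m for m in members if m not in present]
        return hit, missing


@dataclass
class ProbMatrix:
    """Per-cell probability simplex over cell-type labels.

    Every row sums to 1 (within ``PROB_SIMPLEX_TOL``) and entries lie in
    [0, 1]. This is the object all plasticity statistics consume.
    """

    probs: np.ndarray
    cell_ids: np.ndarray
    class_labels: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        n, k = self.probs.shape
        if n != len(self.cell_ids) or k != len(self.class_labels):
            raise DataValidationError("probability matrix dims do not match ids")
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.class_labels, "class labels")
        if self.probs.size:
            if self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9:
                raise DataValidationError("probability entries outside [0, 1]")
            np.clip(self.probs, 0.0, 1.0, out=self.probs)
            dev = np.abs(self.probs.sum(axis=1) - 1.0)
            if dev.size and dev.max() > PROB_SIMPLEX_TOL:
                bad = self.cell_ids[int(np.argmax(dev))]
                raise DataValidationError(
                    f"probability row for cell {bad!r} sums to "
                    f"{1 + dev.max():.6f}, not 1"
                )

    @property
    def n_cells(self) -> int:
        return self.probs.shape[0]

    def column(self, label: str) -> np.ndarray:
        idx = np.nonzero(self.class_labels == label)[0]
        if not idx.size:
            raise KeyError(f"unknown class label {label!r}")
        return self.probs[:, idx[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=pd.Index(self.cell_ids, name="cell_id"),
                            columns=list(self.class_labels))

    def subset(self, cell_ids: np.ndarray) -> "ProbMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            rows = np.array([pos[c] for c in cell_ids], dtype=int)
        except KeyError as exc:
            raise DataValidationError(f"cell {exc.args[0]!r} not in probability matrix") from exc
        return ProbMatrix(self.probs[rows].copy(), np.asarray(cell_ids, dtype=object),
                          self.class_labels)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_id_file(path: str | Path, what: str) -> np.ndarray:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    if not ids:
        raise DataValidationError(f"{what} file {path} is empty")
    return np.asarray(ids, dtype=object)


def read_expression(matrix_path: str | Path, cells_path: str | Path,
                    genes_path: str | Path, layer_tag: str = RAW_COUNTS) -> ExpressionMatrix:
    """Read a Matrix Market matrix with cell/gene id side files.

    Sparse input is preserved as CSR. Dimension mismatches between the matrix
    and the id files are fatal, with the offending counts reported.
    """
    mat = mmread(str(matrix_path))
    if sparse.issparse(mat):
        mat = mat.tocsr()
    else:
        mat = np.asarray(mat)
    cells = _read_id_file(cells_path, "cell id")
    genes = _read_id_file(genes_path, "gene id")
    n, g = mat.shape
    if n != len(cells) or g != len(genes):
        raise DataValidationError(
            f"matrix {matrix_path} is {n} x {g} but id files declare "
            f"{len(cells)} cells and {len(genes)} genes"
        )
    return ExpressionMatrix(mat, cells, genes, layer_tag)


def write_expression(expr: ExpressionMatrix, directory: str | Path,
                     meta: dict | None = None) -> Path:
    """Write matrix.mtx + cells.tsv + genes.tsv + manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mtx = directory / "matrix.mtx"
    vals = expr.values
    if not sparse.issparse(vals):
        vals = sparse.coo_matrix(vals)
    buf = io.BytesIO()
    mmwrite(buf, vals.tocoo(), precision=17)
    atomic_write_bytes(mtx, buf.getvalue())
    cells = directory / "cells.tsv"
    genes = directory / "genes.tsv"
    atomic_write_text(cells, "\n".join(map(str, expr.cell_ids)) + "\n")
    atomic_write_text(genes, "\n".join(map(str, expr.gene_ids)) + "\n")
    meta = dict(meta or {})
    meta.setdefault("layer_tag", expr.layer_tag)
    meta.setdefault("shape", [int(expr.n_cells), int(expr.n_genes)])
    return write_manifest(directory, [mtx, cells, genes], meta=meta)


def read_expression_csv(csv_path: str | Path, layer_tag: str = RAW_COUNTS) -> ExpressionMatrix:
    """Dense CSV alternative: first column cell ids, header gene ids."""
    df = pd.read_csv(csv_path, index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=float),
                            df.index.to_numpy(object),
                            df.columns.to_numpy(object), layer_tag)


def write_expression_csv(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.to_dense(), index=pd.Index(expr.cell_ids, name="cell_id"),
                      columns=list(expr.gene_ids))
    atomic_write_text(path, df.to_csv())


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def read_cell_table(path: str | Path, vocabulary: tuple[str, ...] = ()) -> CellTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CellTable(df, vocabulary=vocabulary)


def write_cell_table(table: CellTable, path: str | Path) -> None:
    atomic_write_text(path, table.df.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(gmt_path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Mixed-whitespace member separators are tolerated; duplicate genes within
    a set are removed (first occurrence kept); an empty member list rejects
    that set with a warning; a duplicate set name is fatal.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
                parts = [parts[0], ""] + parts[1:]
            name, desc = parts[0].strip(), parts[1].strip()
            members: list[str] = []
            for fieldval in parts[2:]:
                members.extend(fieldval.split())
            deduped = list(dict.fromkeys(m for m in members if m))
            if name in sets:
                raise DataValidationError(
                    f"duplicate gene-set name {name!r} at line {lineno} of {gmt_path}"
                )
            if not deduped:
                warnings.warn(f"gene set {name!r} has no members and was skipped")
                continue
            sets[name] = deduped
            descriptions[name] = desc
            logger.info("gene set %s: %d genes", name, len(deduped))
    if not sets:
        raise DataValidationError(f"no usable gene sets in {gmt_path}")
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + collection.sets[name])
        for name in collection.sets
    ]
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# probability tables
# ---------------------------------------------------------------------------

def read_probability_table(csv_path: str | Path) -> ProbMatrix:
    """Ingest a per-cell probability CSV (header = class labels).

    Rows whose sum is within ``PROB_ROW_SUM_TOL`` of 1 are renormalized to
    sum exactly 1; larger deviations are fatal, naming the offending cell.
    """
    df = pd.read_csv(csv_path, index_col=0)
    probs = df.to_numpy(dtype=float)
    if probs.size:
        if probs.min() < -1e-9 or probs.max() > 1 + 1e-9:
            r, c = np.unravel_index(int(np.argmax(np.abs(probs - 0.5))), probs.shape)
            raise DataValidationError(
                f"probability entry {probs[r, c]!r} for cell {df.index[r]!r} "
                "is outside [0, 1]"
            )
        sums = probs.sum(axis=1)
        dev = np.abs(sums - 1.0)
        if dev.max() > PROB_ROW_SUM_TOL:
            bad = df.index[int(np.argmax(dev))]
            raise DataValidationError(
                f"probability row for cell {bad!r} sums to "
                f"{sums[int(np.argmax(dev))]:.6f}; deviation exceeds {PROB_ROW_SUM_TOL}"
            )
        probs = probs / sums[:, None]
    return ProbMatrix(probs, df.index.to_numpy(object), df.columns.to_numpy(object))


def write_probability_table(prob: ProbMatrix, path: str | Path) -> None:
    atomic_write_text(path, prob.to_frame().to_csv(float_format="%.12g"))
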