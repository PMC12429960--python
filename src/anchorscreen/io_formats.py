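"""Readers, writers and validated in-memory containers for every external format
the screen touches.

Formats handled:

* counts TSV (gene-id first column, one column per sample) plus a sample sheet
  TSV with columns ``sample``, ``dataset``, ``timepoint``, ``replicate``;
* GMT gene-set files (set name, description, members, tab-separated);
* MatrixMarket single-cell triplets (``matrix.mtx`` + ``features.tsv`` +
  ``barcodes.tsv``) with an ``annotations.tsv`` carrying per-cell ``cell_type``
  and ``stage``;
* result tables written as TSV with a JSON run summary.

Loading is strict: duplicate or missing identifiers, non-integer counts and
dimension mismatches raise :class:`LoadError` naming the offending record.
Gene and sample order is always preserved as given.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class AnchorscreenError(Exception):
    """Base class for all errors raised by this package."""


class LoadError(AnchorscreenError):
    """An input file is malformed or inconsistent with its companions."""


class ValidationError(AnchorscreenError):
    """An in-memory object violates a container invariant."""


SAMPLESHEET_COLUMNS = ("sample", "dataset", "timepoint", "replicate")
ANNOTATION_COLUMNS = ("barcode", "cell_type", "stage")


def normalize_symbol(symbol: str, mapping: Mapping[str, str] | None = None) -> str:
    """Normalize a gene symbol for cross-dataset matching.

    Matching is case-insensitive exact-symbol by default (symbols are
    uppercased); an optional ``mapping`` (alias -> canonical symbol, matched
    case-insensitively) supports ortholog/alias resolution across species.
    """
    s = str(symbol).strip().upper()
    if mapping:
        s = str(mapping.get(s, s)).strip().upper()
    return s


def read_symbol_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (alias, canonical) into an uppercased mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise LoadError(f"mapping file {path} needs two tab-separated columns")
    return {
        str(a).strip().upper(): str(b).strip().upper()
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Raw gene x sample integer counts with per-sample design labels.

    ``sample_meta`` is indexed by sample id and carries ``dataset``,
    ``timepoint`` (0-based ordered index within its dataset),
    ``timepoint_label`` (the original label) and ``replicate``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)) or np.any(
                self.counts != np.floor(self.counts)
            ):
                raise ValidationError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        missing = [s for s in self.sample_ids if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"samples missing from sample_meta: {missing}")
        self.sample_meta = self.sample_meta.loc[self.sample_ids]
        for ds, sub in self.sample_meta.groupby("dataset", sort=False):
            tps = sorted(sub["timepoint"].unique())
            if tps != list(range(len(tps))):
                raise ValidationError(
                    f"dataset {ds}: timepoints {tps} are not contiguous 0..T-1"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def datasets(self) -> list[str]:
        return list(self.sample_meta["dataset"].unique())

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
            sample_meta=self.sample_meta.loc[list(sample_ids)].copy(),
        )

    def for_dataset(self, dataset_id: str) -> "CountMatrix":
        keep = self.sample_meta.index[self.sample_meta["dataset"] == dataset_id]
        if len(keep) == 0:
            raise KeyError(f"dataset {dataset_id!r} not present")
        return self.subset_samples(list(keep))


def read_counts(counts_path: str | Path, samplesheet_path: str | Path) -> CountMatrix:
    """Load a counts TSV plus its sample sheet into a validated CountMatrix.

    Timepoint labels in the sheet are re-indexed to 0..T-1 per dataset in
    their order of first appearance; original labels are kept in
    ``timepoint_label``.
    """
    counts_df = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samplesheet_path, sep="\t", dtype=str)
    missing_cols = [c for c in SAMPLESHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise LoadError(
            f"sample sheet {samplesheet_path} is missing columns {missing_cols}"
        )
    sheet_samples = list(sheet["sample"])
    header_samples = list(counts_df.columns)
    absent = [s for s in sheet_samples if s not in header_samples]
    if absent:
        raise LoadError(
            f"samples in sheet but not in counts header: {absent}"
        )
    unlisted = [s for s in header_samples if s not in sheet_samples]
    if unlisted:
        raise LoadError(f"samples in counts header but not in sheet: {unlisted}")

    values = counts_df[sheet_samples].to_numpy()
    bad = ~np.isfinite(values.astype(float)) | (
        values.astype(float) != np.floor(values.astype(float))
    )
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise LoadError(
            f"non-integer count {values[g, s]!r} at gene "
            f"{counts_df.index[g]!r}, sample {sheet_samples[s]!r}"
        )
    values = values.astype(np.int64)
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise LoadError(
            f"negative count at gene {counts_df.index[g]!r}, "
            f"sample {sheet_samples[s]!r}"
        )

    meta = sheet.set_index("sample")
    meta["timepoint_label"] = meta["timepoint"]
    tp_index = np.empty(len(meta), dtype=np.int64)
    for ds, sub in meta.groupby("dataset", sort=False):
        order: dict[str, int] = {}
        for lbl in sub["timepoint_label"]:
            order.setdefault(lbl, len(order))
        tp_index[meta.index.get_indexer(sub.index)] = [
            order[lbl] for lbl in sub["timepoint_label"]
        ]
    meta["timepoint"] = tp_index

    return CountMatrix(
        gene_ids=[str(g) for g in counts_df.index],
        sample_ids=sheet_samples,
        counts=values,
        sample_meta=meta[["dataset", "timepoint", "timepoint_label", "replicate"]],
    )


def write_counts(cm: CountMatrix, counts_path: str | Path, samplesheet_path: str | Path) -> None:
    """Write a CountMatrix back to a counts TSV + sample sheet pair."""
    df = pd.DataFrame(cm.counts, index=pd.Index(cm.gene_ids, name="gene"),
                      columns=cm.sample_ids)
    df.to_csv(counts_path, sep="\t")
    sheet = cm.sample_meta.reset_index(names="sample")
    sheet = sheet.assign(timepoint=sheet["timepoint_label"])
    sheet[list(SAMPLESHEET_COLUMNS)].to_csv(samplesheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneSet / GMT
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols, normalized for matching."""

    name: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.members

    def __len__(self) -> int:
        return len(self.members)


def make_gene_set(
    name: str,
    members: Iterable[str],
    source: str = "",
    mapping: Mapping[str, str] | None = None,
) -> GeneSet:
    return GeneSet(
        name=name,
        members=frozenset(normalize_symbol(m, mapping) for m in members),
        source=source,
    )


def read_gmt(path: str | Path, mapping: Mapping[str, str] | None = None) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3"
                )
            name, desc = fields[0], fields[1]
            members = [f for f in fields[2:] if f]
            if not members:
                raise LoadError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(make_gene_set(name, members, source=desc, mapping=mapping))
    if not sets:
        raise LoadError(f"{path}: GMT file contains no gene sets")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source or "na", *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# CellMatrix / MatrixMarket
# ---------------------------------------------------------------------------


@dataclass
class CellMatrix:
    """Sparse normalized single-cell expression (cells x genes) with per-cell
    ``cell_type`` and ``stage`` annotations."""

    cell_ids: list[str]
    gene_ids: list[str]
    expr: sp.csr_matrix
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.expr = sp.csr_matrix(self.expr)
        if self.expr.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"expr shape {self.expr.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.expr.nnz and self.expr.data.min() < 0:
            raise ValidationError("expression values must be non-negative")
        for col in ("cell_type", "stage"):
            if col not in self.cell_meta.columns:
                raise ValidationError(f"cell_meta is missing column {col!r}")
        missing = [c for c in self.cell_ids if c not in self.cell_meta.index]
        if missing:
            raise ValidationError(f"cells without annotations: {missing[:5]}")
        self.cell_meta = self.cell_meta.loc[self.cell_ids]

    @property
    def shape(self) -> tuple[int, int]:
        return self.expr.shape

    @property
    def n_cells(self) -> int:
        return self.expr.shape[0]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        mask = np.asarray(mask, dtype=bool)
        ids = [c for c, m in zip(self.cell_ids, mask) if m]
        return CellMatrix(
            cell_ids=ids,
            gene_ids=list(self.gene_ids),
            expr=self.expr[mask],
            cell_meta=self.cell_meta.loc[ids].copy(),
        )

    def to_anndata(self):
        """View as an :class:`anndata.AnnData` (cells x genes)."""
        import anndata

        return anndata.AnnData(
            X=self.expr.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )


def read_cellmatrix(mtx_dir: str | Path) -> CellMatrix:
    """Load ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` +
    ``annotations.tsv`` from a directory.

    The matrix follows the 10x convention of genes (features) as rows and
    cells (barcodes) as columns; it is transposed to cells x genes on load.
    ``annotations.tsv`` must cover every barcode and carry ``cell_type`` and
    ``stage`` columns.
    """
    mtx_dir = Path(mtx_dir)
    paths = {name: mtx_dir / name for name in
             ("matrix.mtx", "features.tsv", "barcodes.tsv", "annotations.tsv")}
    absent = [str(p) for p in paths.values() if not p.exists()]
    if absent:
        raise LoadError(f"missing single-cell input files: {absent}")

    mat = sp.csr_matrix(scipy.io.mmread(paths["matrix.mtx"]).T)
    features = pd.read_csv(paths["features.tsv"], sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(paths["barcodes.tsv"], sep="\t", header=None, dtype=str)
    gene_ids = list(features.iloc[:, 0])
    cell_ids = list(barcodes.iloc[:, 0])
    if mat.shape != (len(cell_ids), len(gene_ids)):
        raise LoadError(
            f"matrix.mtx is {mat.shape[1]} genes x {mat.shape[0]} cells but "
            f"features.tsv has {len(gene_ids)} and barcodes.tsv has {len(cell_ids)}"
        )

    ann = pd.read_csv(paths["annotations.tsv"], sep="\t", dtype=str)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise LoadError(f"annotations.tsv is missing columns {missing_cols}")
    ann = ann.set_index("barcode")
    stray = [b for b in ann.index if b not in set(cell_ids)]
    if stray:
        raise LoadError(f"annotated barcodes absent from matrix: {stray[:5]}")
    unannotated = [b for b in cell_ids if b not in ann.index]
    if unannotated:
        raise LoadError(f"barcodes without annotations: {unannotated[:5]}")

    return CellMatrix(cell_ids=cell_ids, gene_ids=gene_ids, expr=mat,
                      cell_meta=ann)


def write_cellmatrix(cells: CellMatrix, mtx_dir: str | Path) -> None:
    """Write a CellMatrix as the four-file MatrixMarket layout read_cellmatrix expects."""
    mtx_dir = Path(mtx_dir)
    mtx_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(mtx_dir / "matrix.mtx"), sp.coo_matrix(cells.expr.T))
    pd.Series(cells.gene_ids).to_csv(mtx_dir / "features.tsv", sep="\t",
                                     index=False, header=False)
    pd.Series(cells.cell_ids).to_csv(mtx_dir / "barcodes.tsv", sep="\t",
                                     index=False, header=False)
    ann = cells.cell_meta.reset_index(names="barcode")
    ann.to_csv(mtx_dir / "annotations.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result output
# ---------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    parameters: Mapping | None = None,
    overwrite: bool = False,
) -> dict:
    """Write each named table as ``<name>.tsv`` plus a ``summary.json``.

    The summary records parameters, versions and per-table row counts so a
    run can be reconstructed from its output directory alone. Returns a
    manifest listing the files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    targets = {name: out_dir / f"{name}.tsv" for name in tables}
    targets["__summary__"] = out_dir / "summary.json"
    if not overwrite:
        existing = [str(p) for p in targets.values() if p.exists()]
        if existing:
            raise AnchorscreenError(
                f"output files already exist (pass overwrite=True): {existing}"
            )
    written = []
    row_counts = {}
    for name, df in tables.items():
        path = targets[name]
        df.to_csv(path, sep="\t", index=False)
        written.append(str(path))
        row_counts[name] = int(len(df))
    summary = {
        "parameters": dict(parameters or {}),
        "row_counts": row_counts,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": written,
    }
    summary_path = targets["__summary__"]
    summary_path.write_text(json.dumps(summary, indent=2, default=str) + "\n")
    written.append(str(summary_path))
    return {"out_dir": str(out_dir), "files": written, "row_counts": row_counts}
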