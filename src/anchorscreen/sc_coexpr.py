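"""Single-cell co-expression and mutual-exclusivity analysis.

Works on a :class:`~anchorscreen.io_formats.CellMatrix` of normalized
expression with per-cell ``cell_type`` and ``stage`` annotations (cell typing
is taken as given, as when reusing a public object's original annotations).
Stages are filtered to the postnatal window of interest, dot-plot statistics
summarize each gene per cell type (fraction of cells expressing it and mean
normalized expression over all cells of the type), and co-expression of an
anchor/candidate pair is counted cell by cell within one cell type.

A cell "expresses" a gene when its normalized value exceeds a threshold,
default 0 (strictly positive), configurable via ``threshold``.

The permutation mutual-exclusivity test goes beyond descriptive counting: it
asks how often a random relabeling of which cells express gene B (within the
cell type, preserving the number of expressing cells) yields at most the
observed number of double-positive cells. Outputs flag it as an extension of
the descriptive overlap count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AnchorscreenError, CellMatrix


def filter_stages(cells: CellMatrix, stages: list[str]) -> CellMatrix:
    """Restrict to cells whose ``stage`` annotation is in ``stages``.

    Every requested stage must exist in the annotations; an empty result
    (listed stages present but no cell retained) is valid.
    """
    available = set(cells.cell_meta["stage"].unique())
    missing = [s for s in stages if s not in available]
    if missing:
        raise AnchorscreenError(
            f"stage(s) {missing} not present; available stages: {sorted(available)}"
        )
    mask = cells.cell_meta["stage"].isin(stages).to_numpy()
    return cells.subset_cells(mask)


@dataclass
class DotPlotStat:
    """Per cell-type summary of one gene: percentage of cells expressing it
    and mean normalized expression over all cells of the type."""

    group: str
    gene: str
    n_cells: int
    pct_expressing: float
    mean_expr: float


def dotplot_stats(
    cells: CellMatrix,
    genes: list[str],
    group_by: str = "cell_type",
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Dot-plot statistics per annotation group and gene.

    ``pct_expressing`` is the percentage of group cells with value >
    ``threshold``; ``mean_expr`` averages the normalized values over ALL
    cells of the group, zeros included.
    """
    if group_by not in cells.cell_meta.columns:
        raise AnchorscreenError(f"annotation column {group_by!r} not present")
    gidx = [cells.gene_index(g) for g in genes]
    sub = cells.expr[:, gidx].toarray()
    groups = cells.cell_meta[group_by].to_numpy()
    rows = []
    for grp in pd.unique(groups):
        mask = groups == grp
        block = sub[mask]
        n = int(mask.sum())
        for j, gene in enumerate(genes):
            col = block[:, j]
            rows.append(DotPlotStat(
                group=str(grp), gene=gene, n_cells=n,
                pct_expressing=100.0 * float((col > threshold).sum()) / n,
                mean_expr=float(col.mean()),
            ))
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class CoexpressionCounts:
    """Counts of cells expressing gene A and/or gene B within one cell type,
    overall and per developmental stage."""

    gene_a: str
    gene_b: str
    cell_type: str
    threshold: float
    n_total: int
    n_a_only: int
    n_b_only: int
    n_both: int
    stage_breakdown: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_total != self.n_a_only + self.n_b_only + self.n_both:
            raise AnchorscreenError(
                "co-expression counts violate n_total = a_only + b_only + both"
            )
        for stage, c in self.stage_breakdown.items():
            if c["n_total"] != c["n_a_only"] + c["n_b_only"] + c["n_both"]:
                raise AnchorscreenError(f"stage {stage}: count identity violated")

    def as_dict(self) -> dict:
        return {
            "gene_a": self.gene_a, "gene_b": self.gene_b,
            "cell_type": self.cell_type, "threshold": self.threshold,
            "n_total": self.n_total, "n_a_only": self.n_a_only,
            "n_b_only": self.n_b_only, "n_both": self.n_both,
            "stage_breakdown": self.stage_breakdown,
        }


def coexpression_counts(
    cells: CellMatrix,
    gene_a: str,
    gene_b: str,
    cell_type: str,
    threshold: float = 0.0,
) -> CoexpressionCounts:
    """Classify every cell of one type by (expresses A, expresses B).

    ``n_total`` counts cells expressing A and/or B; the per-stage breakdown
    sums to the totals by construction.
    """
    types = cells.cell_meta["cell_type"].to_numpy()
    if cell_type not in set(types):
        raise AnchorscreenError(
            f"cell type {cell_type!r} not present; available: {sorted(set(types))}"
        )
    mask = types == cell_type
    ia, ib = cells.gene_index(gene_a), cells.gene_index(gene_b)
    va = cells.expr[:, ia].toarray().ravel()[mask] > threshold
    vb = cells.expr[:, ib].toarray().ravel()[mask] > threshold
    stages = cells.cell_meta["stage"].to_numpy()[mask]

    def tally(a: np.ndarray, b: np.ndarray) -> dict[str, int]:
        both = int((a & b).sum())
        a_only = int((a & ~b).sum())
        b_only = int((~a & b).sum())
        return {
            "n_total": a_only + b_only + both,
            "n_a_only": a_only, "n_b_only": b_only, "n_both": both,
        }

    overall = tally(va, vb)
    breakdown = {}
    for stage in pd.unique(stages):
        sm = stages == stage
        breakdown[str(stage)] = tally(va[sm], vb[sm])
    return CoexpressionCounts(
        gene_a=gene_a, gene_b=gene_b, cell_type=cell_type, threshold=threshold,
        stage_breakdown=breakdown, **overall,
    )


def exclusivity_test(
    cells: CellMatrix,
    gene_a: str,
    gene_b: str,
    cell_type: str,
    n_perm: int = 1000,
    seed: int | None = None,
    threshold: float = 0.0,
) -> float:
    """Permutation p-value for mutual exclusivity of two genes in a cell type.

    Holds which cells express A fixed, redraws the set of B-expressing cells
    uniformly at random (same size) within the cell type, and reports the
    fraction of permutations with n_both <= observed, with the add-one
    correction (k+1)/(n_perm+1). Small p means fewer double-positive cells
    than expected if the genes were expressed independently. Returns NaN when
    either gene is expressed in no cell of the type (the test is degenerate).
    """
    if n_perm < 100:
        raise AnchorscreenError(f"n_perm must be >= 100, got {n_perm}")
    types = cells.cell_meta["cell_type"].to_numpy()
    if cell_type not in set(types):
        raise AnchorscreenError(f"cell type {cell_type!r} not present")
    mask = types == cell_type
    ia, ib = cells.gene_index(gene_a), cells.gene_index(gene_b)
    va = cells.expr[:, ia].toarray().ravel()[mask] > threshold
    vb = cells.expr[:, ib].toarray().ravel()[mask] > threshold
    n_cells = int(mask.sum())
    n_a, n_b = int(va.sum()), int(vb.sum())
    if n_a == 0 or n_b == 0:
        return float("nan")
    observed = int((va & vb).sum())
    rng = np.random.default_rng(seed)
    a_idx = np.flatnonzero(va)
    hits = 0
    for _ in range(n_perm):
        b_perm = rng.choice(n_cells, size=n_b, replace=False)
        overlap = np.isin(b_perm, a_idx).sum()
        if overlap <= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def cp10k_log1p(cells: CellMatrix) -> CellMatrix:
    """Library-size normalize raw counts to counts-per-10k and log1p them.

    Helper for raw-count inputs; the pipeline otherwise takes normalization
    as given. Cells with zero totals are left at zero.
    """
    expr = cells.expr.astype(float).tocsr(copy=True)
    totals = np.asarray(expr.sum(axis=1)).ravel()
    scale = np.divide(1e4, totals, out=np.zeros_like(totals), where=totals > 0)
    expr = expr.multiply(scale[:, None]).tocsr()
    expr.data = np.log1p(expr.data)
    return CellMatrix(
        cell_ids=list(cells.cell_ids),
        gene_ids=list(cells.gene_ids),
        expr=expr,
        cell_meta=cells.cell_meta.copy(),
    )
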