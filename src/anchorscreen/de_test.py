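"""Negative-binomial Wald differential expression across the drop transition.

A deliberately transparent two-group NB test: median-of-ratios size factors,
per-gene method-of-moments dispersion pooled across the two groups, a Wald
statistic on the log2 fold change with the standard error taken from the
observed Fisher information, and Benjamini-Hochberg adjustment. There is no
dispersion shrinkage, no fold-change moderation and no independent filtering;
the consensus screen only consumes the adjusted p-value and the sign of the
fold change, which this test provides with known calibration (checked by
simulation in the test suite).

The Wald statistic is referred to a t distribution with the two-group
residual degrees of freedom (n_a + n_b - 2) rather than a normal: with the
tiny replicate numbers typical of developmental time courses (n = 4), the
plug-in dispersion makes the statistic t-like, and a normal reference roughly
doubles the nominal type-I error. With many replicates the two references
coincide.

Constants: dispersion floor 1e-8; pseudo-quantity 0.5 normalized counts added
to both group means when either is zero (keeps the fold change finite).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import AnchorscreenError, CountMatrix

DISPERSION_FLOOR = 1e-8
PSEUDO_QUANTITY = 0.5
LN2 = float(np.log(2.0))


def size_factors(counts: np.ndarray, pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios per-sample normalization constants.

    For each gene with nonzero counts in every sample, compute the ratio of
    each sample's count to the gene's geometric mean; the size factor of a
    sample is the median of these ratios. With ``pseudo_reference=True`` the
    geometric mean is taken over nonzero counts only, rescuing datasets where
    no gene is expressed everywhere (very sparse designs).
    """
    K = np.asarray(counts, dtype=float)
    if K.ndim != 2:
        raise AnchorscreenError("counts must be a genes x samples matrix")
    if pseudo_reference:
        logs = np.zeros_like(K)
        np.log(K, where=K > 0, out=logs)
        n_pos = (K > 0).sum(axis=1)
        usable = n_pos > 0
        if not usable.any():
            raise AnchorscreenError("all counts are zero; cannot compute size factors")
        geo = np.exp(logs[usable].sum(axis=1) / n_pos[usable])
        ratios = np.where(K[usable] > 0, K[usable] / geo[:, None], np.nan)
        s = np.nanmedian(ratios, axis=0)
    else:
        usable = (K > 0).all(axis=1)
        if not usable.any():
            raise AnchorscreenError(
                "no gene has nonzero counts in every sample; "
                "retry with pseudo_reference=True"
            )
        logs = np.log(K[usable])
        geo = np.exp(logs.mean(axis=1))
        s = np.median(K[usable] / geo[:, None], axis=0)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise AnchorscreenError("degenerate size factors; check the count matrix")
    return s


def _mom_dispersion(y: np.ndarray, inv_s: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion from one group of normalized counts.

    For K ~ NB(mean s_j q, dispersion phi), y_j = K_j / s_j has
    Var(y_j) = q / s_j + phi q^2, so phi = (var - q * mean(1/s)) / q^2.
    Returns NaN where the group mean is zero.
    """
    q = y.mean(axis=1)
    v = y.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (v - q * inv_s.mean()) / q**2
    phi = np.where(q > 0, phi, np.nan)
    return phi


def nb_wald(
    counts: np.ndarray | CountMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
    factors: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
    dataset_id: str = "",
    transition: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group B (later timepoint) vs group A.

    ``group_a`` / ``group_b`` are column indices into ``counts``. Size
    factors are computed on the tested samples when not supplied. Genes with
    zero counts in both groups are excluded from testing and from the BH
    denominator (``tested=False``, NaN statistics).

    Returns a DataFrame with columns gene, mean_norm, log2fc, se, wald_p,
    padj, tested.
    """
    if isinstance(counts, CountMatrix):
        if gene_ids is None:
            gene_ids = list(counts.gene_ids)
        counts = counts.counts
    K = np.asarray(counts, dtype=float)
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size < 2 or b.size < 2:
        raise AnchorscreenError(
            f"each group needs >= 2 samples (got {a.size} and {b.size})"
        )
    cols = np.concatenate([a, b])
    if factors is None:
        factors = size_factors(K[:, cols])
        s_a, s_b = factors[: a.size], factors[a.size :]
    else:
        factors = np.asarray(factors, dtype=float)
        s_a, s_b = factors[a], factors[b]

    Ka, Kb = K[:, a], K[:, b]
    ya, yb = Ka / s_a, Kb / s_b
    q_a, q_b = ya.mean(axis=1), yb.mean(axis=1)
    tested = (Ka.sum(axis=1) + Kb.sum(axis=1)) > 0

    # dispersion: method-of-moments per group, pooled by residual df
    phi_a = _mom_dispersion(ya, 1.0 / s_a)
    phi_b = _mom_dispersion(yb, 1.0 / s_b)
    w_a, w_b = a.size - 1, b.size - 1
    phi = np.nansum(
        np.stack([phi_a * w_a * ~np.isnan(phi_a), phi_b * w_b * ~np.isnan(phi_b)]),
        axis=0,
    )
    denom = w_a * ~np.isnan(phi_a) + w_b * ~np.isnan(phi_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = phi / denom
    phi = np.where(np.isfinite(phi), phi, DISPERSION_FLOOR)
    phi = np.maximum(phi, DISPERSION_FLOOR)

    # fold change with pseudo-quantity when either group mean is zero
    zero_either = (q_a == 0) | (q_b == 0)
    qa_eff = np.where(zero_either, q_a + PSEUDO_QUANTITY, q_a)
    qb_eff = np.where(zero_either, q_b + PSEUDO_QUANTITY, q_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(qb_eff / qa_eff)

    # observed Fisher information for the log mean of each group:
    # I = sum_j mu_j / (1 + phi mu_j), mu_j = s_j * q
    mu_a = s_a[None, :] * qa_eff[:, None]
    mu_b = s_b[None, :] * qb_eff[:, None]
    info_a = (mu_a / (1.0 + phi[:, None] * mu_a)).sum(axis=1)
    info_b = (mu_b / (1.0 + phi[:, None] * mu_b)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ln = np.sqrt(1.0 / info_a + 1.0 / info_b)
    se = se_ln / LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    df = a.size + b.size - 2
    wald_p = 2.0 * scipy.stats.t.sf(np.abs(z), df=df)
    wald_p = np.where(log2fc == 0, 1.0, wald_p)

    log2fc = np.where(tested, log2fc, np.nan)
    se = np.where(tested, se, np.nan)
    wald_p = np.where(tested, wald_p, np.nan)
    padj = np.full_like(wald_p, np.nan)
    padj[tested] = bh_adjust(wald_p[tested])

    mean_norm = np.concatenate([ya, yb], axis=1).mean(axis=1)
    out = pd.DataFrame({
        "gene": gene_ids if gene_ids is not None else [f"g{i}" for i in range(K.shape[0])],
        "mean_norm": mean_norm,
        "log2fc": log2fc,
        "se": se,
        "wald_p": wald_p,
        "padj": padj,
        "tested": tested,
    })
    out.attrs["dataset_id"] = dataset_id
    out.attrs["transition"] = transition
    out.attrs["dispersion_floor"] = DISPERSION_FLOOR
    out.attrs["pseudo_quantity"] = PSEUDO_QUANTITY
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank downwards, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise AnchorscreenError("bh_adjust expects a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise AnchorscreenError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def de_for_transition(
    cm: CountMatrix,
    dataset_id: str,
    transition: tuple[int, int],
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Run nb_wald between two timepoints of one dataset of a CountMatrix."""
    sub = cm.for_dataset(dataset_id)
    t_prev, t_drop = transition
    meta = sub.sample_meta
    a = np.flatnonzero(meta["timepoint"].to_numpy() == t_prev)
    b = np.flatnonzero(meta["timepoint"].to_numpy() == t_drop)
    if a.size == 0 or b.size == 0:
        raise AnchorscreenError(
            f"dataset {dataset_id!r} lacks samples at transition {transition}"
        )
    cols = np.concatenate([a, b])
    factors_local = size_factors(sub.counts[:, cols], pseudo_reference=pseudo_reference)
    factors = np.empty(sub.counts.shape[1])
    factors[cols] = factors_local
    return nb_wald(
        sub.counts, a, b, factors=factors, gene_ids=list(sub.gene_ids),
        dataset_id=dataset_id, transition=transition,
    )
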