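"""Bulk time-course screening against an anchor gene.

The screen runs per dataset, left to right:

1. counts -> CPM -> log2(CPM + 4) (variance-stabilized scale used throughout);
2. anchor drop-point detection: one-way ANOVA across timepoint groups,
   then an exact two-sided Wilcoxon test on each consecutive timepoint pair
   (signed-rank pairing replicates by label, or rank-sum treating groups as
   independent); the drop is the earliest significant decrease;
3. per-gene Pearson correlation with the anchor over timepoint means;
4. cross-dataset consensus: keep genes with |r| >= r_min in at least
   min_datasets_r datasets and transition differential expression passing the
   configured rule.

Replicate counts in developmental time courses are tiny (often 4), where
asymptotic Wilcoxon p-values are badly wrong, so small-sample null
distributions are enumerated exactly (ties handled by mid-ranks, conditioning
on the observed values); the normal approximation is used only beyond 25
replicates per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import AnchorscreenError, CountMatrix, ValidationError

EXACT_LIMIT = 25  # per-group size above which the normal approximation kicks in


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizedMatrix:
    """Gene x sample normalized expression; ``transform`` is CPM or LOG2CPM4."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    transform: str
    sample_meta: pd.DataFrame

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None


def cpm(counts: CountMatrix) -> NormalizedMatrix:
    """Counts per million: each column scaled to sum to 1e6."""
    totals = counts.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise AnchorscreenError(
            f"sample(s) with zero total counts: {[counts.sample_ids[i] for i in zero]}"
        )
    values = counts.counts / totals * 1e6
    return NormalizedMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=values,
        transform="CPM",
        sample_meta=counts.sample_meta.copy(),
    )


def log2cpm4(norm: NormalizedMatrix) -> NormalizedMatrix:
    """The screen's variance-stabilizing transform, log2(CPM + 4).

    Zero expression maps to exactly 2.0 (= log2 4), bounding the scale below.
    """
    if norm.transform != "CPM":
        raise AnchorscreenError(
            f"log2cpm4 expects a CPM matrix, got transform={norm.transform!r}"
        )
    return NormalizedMatrix(
        gene_ids=list(norm.gene_ids),
        sample_ids=list(norm.sample_ids),
        values=np.log2(norm.values + 4.0),
        transform="LOG2CPM4",
        sample_meta=norm.sample_meta.copy(),
    )


@dataclass
class TimepointProfile:
    """Per-dataset gene x timepoint means of log2(CPM+4) over replicates."""

    gene_ids: list[str]
    dataset_id: str
    timepoint_means: np.ndarray
    timepoint_labels: list[str]

    @property
    def n_timepoints(self) -> int:
        return self.timepoint_means.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None


def timepoint_means(norm: NormalizedMatrix, dataset_id: str | None = None) -> TimepointProfile:
    """Average replicates within each timepoint of one dataset."""
    if norm.transform != "LOG2CPM4":
        raise AnchorscreenError(
            f"timepoint_means expects LOG2CPM4 values, got {norm.transform!r}"
        )
    meta = norm.sample_meta
    if dataset_id is None:
        datasets = list(meta["dataset"].unique())
        if len(datasets) != 1:
            raise AnchorscreenError(
                f"matrix holds datasets {datasets}; pass dataset_id explicitly"
            )
        dataset_id = datasets[0]
    sub = meta[meta["dataset"] == dataset_id]
    if sub.empty:
        raise AnchorscreenError(f"dataset {dataset_id!r} not present")
    tps = sorted(sub["timepoint"].unique())
    if len(tps) < 2:
        raise AnchorscreenError(
            f"dataset {dataset_id!r} has {len(tps)} timepoint(s); need >= 2"
        )
    cols = {s: i for i, s in enumerate(norm.sample_ids)}
    means = np.empty((len(norm.gene_ids), len(tps)))
    labels = []
    for t in tps:
        samples = sub.index[sub["timepoint"] == t]
        if len(samples) == 0:
            raise AnchorscreenError(f"timepoint {t} of {dataset_id!r} has no samples")
        idx = [cols[s] for s in samples]
        means[:, t] = norm.values[:, idx].mean(axis=1)
        labels.append(str(sub.loc[samples[0], "timepoint_label"]))
    return TimepointProfile(
        gene_ids=list(norm.gene_ids),
        dataset_id=dataset_id,
        timepoint_means=means,
        timepoint_labels=labels,
    )


# ---------------------------------------------------------------------------
# Exact small-sample Wilcoxon machinery
# ---------------------------------------------------------------------------


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks doubled so tied (half-integer) ranks become exact integers."""
    ranks = scipy.stats.rankdata(values, method="average")
    doubled = np.round(ranks * 2).astype(np.int64)
    return doubled


def _two_sided_p(dist: np.ndarray, observed: int) -> float:
    """Two-sided p from an exact null pmf over statistic values 0..len-1:
    twice the smaller tail, capped at 1."""
    total = dist.sum()
    lo = dist[: observed + 1].sum() / total
    hi = dist[observed:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def _signed_rank_null(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact null pmf of the doubled positive-rank sum under random sign flips.

    Dynamic programming over the generating function  prod_i (1 + x^{r_i}),
    which enumerates all 2^n sign patterns without listing them; valid with
    mid-ranks because the test conditions on the observed |differences|.
    """
    top = int(doubled_ranks.sum())
    dist = np.zeros(top + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: top + 1 - r]
        dist = dist + shifted
    return dist


def _rank_sum_null(pooled_doubled: np.ndarray, n1: int) -> np.ndarray:
    """Exact null pmf of the doubled rank sum of a size-n1 group drawn without
    replacement from the pooled doubled mid-ranks (conditions on observed ties)."""
    top = int(pooled_doubled.sum())
    dist = np.zeros((n1 + 1, top + 1))
    dist[0, 0] = 1.0
    for r in pooled_doubled:
        # iterate group size downwards so each rank is used at most once
        for k in range(min(n1, 1_000_000), 0, -1):
            dist[k, r:] += dist[k - 1, : top + 1 - r]
    return dist[n1]


def exact_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns ``(W_plus, p)``. Zero differences are dropped (standard
    convention); ties get mid-ranks with the null enumerated exactly over all
    sign patterns for n <= 25 pairs, normal approximation beyond. With every
    difference zero the test is vacuous and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AnchorscreenError("signed-rank test needs equal-length paired samples")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    doubled = _doubled_midranks(np.abs(d))
    w2_plus = int(doubled[d > 0].sum())
    if n <= EXACT_LIMIT:
        dist = _signed_rank_null(doubled)
        p = _two_sided_p(dist, w2_plus)
    else:
        res = scipy.stats.wilcoxon(d, alternative="two-sided", method="approx")
        p = float(res.pvalue)
    return w2_plus / 2.0, p


def exact_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on independent samples.

    Returns ``(rank_sum_of_x, p)``. Exact enumeration (DP over the observed
    mid-ranks, hence tie-correct) for groups up to 25 each; normal
    approximation beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AnchorscreenError("rank-sum test needs two non-empty groups")
    pooled = np.concatenate([x, y])
    doubled = _doubled_midranks(pooled)
    w2 = int(doubled[: x.size].sum())
    if max(x.size, y.size) <= EXACT_LIMIT:
        if np.ptp(pooled) == 0:
            return w2 / 2.0, 1.0
        dist = _rank_sum_null(doubled, x.size)
        p = _two_sided_p(dist, w2)
    else:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return w2 / 2.0, p


def min_attainable_p(test: str, n1: int, n2: int | None = None) -> float:
    """Smallest two-sided p the exact test can produce at the given sample
    sizes (assuming no ties and, for signed-rank, no zero differences).

    At n1 = 4 signed-rank pairs this is 2/2^4 = 0.125 — above the usual 0.05,
    so no transition can be called significant from 4 pairs by this test.
    """
    if test == "signed_rank":
        if n1 < 1:
            raise AnchorscreenError("need at least one pair")
        doubled = 2 * np.arange(1, n1 + 1)
        dist = _signed_rank_null(doubled)
    elif test == "rank_sum":
        if n2 is None:
            n2 = n1
        doubled = 2 * np.arange(1, n1 + n2 + 1)
        dist = _rank_sum_null(doubled, n1)
    else:
        raise AnchorscreenError(f"unknown test {test!r}")
    support = np.flatnonzero(dist)
    return min(_two_sided_p(dist, int(w)) for w in support)


# ---------------------------------------------------------------------------
# Drop detection
# ---------------------------------------------------------------------------


@dataclass
class Transition:
    """Result of testing one consecutive timepoint pair (t-1 -> t)."""

    timepoint: int  # index of the later timepoint
    label: str
    p: float
    min_p: float  # smallest p attainable at these sample sizes
    direction: str  # decrease / increase / none
    mean_delta: float


@dataclass
class DropDetection:
    """Anchor-gene transition scan: ANOVA across all timepoints, exact
    Wilcoxon per consecutive pair, and the called drop timepoint."""

    anchor: str
    dataset_id: str
    anova_p: float
    anova_defined: bool
    transitions: list[Transition]
    drop_index: int | None
    alpha: float
    test: str
    direction: str = "decrease"


def detect_drop(
    norm: NormalizedMatrix,
    anchor: str,
    alpha: float = 0.05,
    test: str = "signed_rank",
    dataset_id: str | None = None,
    direction: str = "decrease",
) -> DropDetection:
    """Locate the earliest timepoint at which the anchor changes significantly
    in the requested direction relative to the immediately preceding one.

    ``test='signed_rank'`` pairs replicates across the two timepoints by
    replicate label (refusing to run when labels do not align);
    ``test='rank_sum'`` treats the groups as independent. A constant anchor
    yields an undefined ANOVA and no drop.
    """
    if test not in ("signed_rank", "rank_sum"):
        raise AnchorscreenError(f"unknown test {test!r}")
    if direction not in ("decrease", "increase"):
        raise AnchorscreenError(f"direction must be decrease or increase, got {direction!r}")
    meta = norm.sample_meta
    if dataset_id is None:
        datasets = list(meta["dataset"].unique())
        if len(datasets) != 1:
            raise AnchorscreenError(
                f"matrix holds datasets {datasets}; pass dataset_id explicitly"
            )
        dataset_id = datasets[0]
    sub = meta[meta["dataset"] == dataset_id]
    gi = norm.gene_index(anchor)
    cols = {s: i for i, s in enumerate(norm.sample_ids)}

    tps = sorted(sub["timepoint"].unique())
    groups: list[np.ndarray] = []
    labels: list[str] = []
    reps: list[list[str]] = []
    for t in tps:
        rows = sub[sub["timepoint"] == t]
        if len(rows) < 2:
            raise AnchorscreenError(
                f"timepoint {t} of {dataset_id!r} has {len(rows)} replicate(s); need >= 2"
            )
        order = np.argsort(rows["replicate"].to_numpy())
        idx = [cols[s] for s in rows.index[order]]
        groups.append(norm.values[gi, idx])
        labels.append(str(rows["timepoint_label"].iloc[0]))
        reps.append([str(r) for r in rows["replicate"].to_numpy()[order]])

    allvals = np.concatenate(groups)
    constant = np.ptp(allvals) == 0
    if constant:
        anova_p, anova_defined = float("nan"), False
    else:
        anova_p = float(scipy.stats.f_oneway(*groups).pvalue)
        anova_defined = bool(np.isfinite(anova_p))

    transitions: list[Transition] = []
    for t in range(1, len(groups)):
        prev, curr = groups[t - 1], groups[t]
        if test == "signed_rank":
            if sorted(reps[t - 1]) != sorted(reps[t]):
                raise AnchorscreenError(
                    f"replicate labels differ between timepoints {t-1} and {t} of "
                    f"{dataset_id!r}; signed_rank needs matched pairs — use test='rank_sum'"
                )
            _, p = exact_signed_rank(curr, prev)
            min_p = min_attainable_p("signed_rank", len(curr))
        else:
            _, p = exact_rank_sum(curr, prev)
            min_p = min_attainable_p("rank_sum", len(curr), len(prev))
        delta = float(curr.mean() - prev.mean())
        if constant or delta == 0:
            dirn = "none"
        else:
            dirn = "decrease" if delta < 0 else "increase"
        transitions.append(Transition(
            timepoint=t, label=labels[t], p=p, min_p=min_p,
            direction=dirn, mean_delta=delta,
        ))

    drop_index = None
    for tr in transitions:
        if tr.p <= alpha and tr.direction == direction:
            drop_index = tr.timepoint
            break
    return DropDetection(
        anchor=anchor, dataset_id=dataset_id, anova_p=anova_p,
        anova_defined=anova_defined, transitions=transitions,
        drop_index=drop_index, alpha=alpha, test=test, direction=direction,
    )


# ---------------------------------------------------------------------------
# Anchor correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationTable:
    """Per-gene Pearson correlation with the anchor over timepoint means."""

    dataset_id: str
    anchor: str
    table: pd.DataFrame  # columns: gene, r, n_timepoints, defined


def correlate_with_anchor(profile: TimepointProfile, anchor: str) -> CorrelationTable:
    """Pearson r between each gene's timepoint-mean trajectory and the
    anchor's, computed on log2(CPM+4) means.

    Genes (or an anchor) with zero variance across timepoints get
    ``defined=False`` and are excluded from downstream threshold filters; the
    anchor correlates with itself at exactly 1.
    """
    T = profile.n_timepoints
    if T < 3:
        raise AnchorscreenError(
            f"dataset {profile.dataset_id!r} has {T} timepoints; need >= 3 for correlation"
        )
    ai = profile.gene_index(anchor)
    M = profile.timepoint_means
    a = M[ai]
    ac = a - a.mean()
    a_ss = float(ac @ ac)
    X = M - M.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", X, X)
    defined = (ss > 0) & (a_ss > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X @ ac) / np.sqrt(ss * a_ss)
    r = np.clip(r, -1.0, 1.0)
    r[~defined] = np.nan
    if a_ss > 0:
        r[ai] = 1.0
    table = pd.DataFrame({
        "gene": profile.gene_ids,
        "r": r,
        "n_timepoints": T,
        "defined": defined,
    })
    return CorrelationTable(dataset_id=profile.dataset_id, anchor=anchor, table=table)


# ---------------------------------------------------------------------------
# Consensus filter
# ---------------------------------------------------------------------------


@dataclass
class ConsensusTable:
    """Cross-dataset consensus: per-gene correlations, DE adjusted p-values
    and pass/fail under the configured thresholds."""

    anchor: str
    table: pd.DataFrame
    thresholds: dict
    n_genes_common: int


def consensus_filter(
    corr_tables: dict[str, CorrelationTable],
    de_tables: dict[str, pd.DataFrame],
    r_min: float = 0.6,
    min_datasets_r: int = 3,
    padj_max: float = 0.05,
    de_rule: str = "all_datasets",
) -> ConsensusTable:
    """Combine per-dataset correlation and DE results into the consensus call.

    A gene passes when |r| >= ``r_min`` in at least ``min_datasets_r``
    datasets AND its transition DE is significant (padj <= ``padj_max``)
    under ``de_rule`` ('all_datasets', or 'min_datasets' meaning at least
    ``min_datasets_r`` datasets). A gene absent from a dataset counts as
    undefined correlation and failed DE there. A dataset may lack a DE table
    entirely (e.g. no anchor drop was detectable in it); it then contributes
    correlation evidence only and counts as a DE failure for every gene.
    Direction summarizes the signs of the threshold-passing correlations.
    """
    if not corr_tables:
        raise AnchorscreenError("consensus_filter needs at least one dataset")
    if not set(de_tables) <= set(corr_tables):
        raise AnchorscreenError(
            f"DE datasets {sorted(set(de_tables) - set(corr_tables))} "
            "have no correlation table"
        )
    if de_rule not in ("all_datasets", "min_datasets"):
        raise AnchorscreenError(f"unknown de_rule {de_rule!r}")
    anchors = {ct.anchor for ct in corr_tables.values()}
    if len(anchors) != 1:
        raise AnchorscreenError(f"correlation tables disagree on anchor: {anchors}")
    (anchor,) = anchors

    datasets = list(corr_tables)
    universe: list[str] = []
    seen: set[str] = set()
    per_ds_genes: list[set[str]] = []
    for ds in datasets:
        genes = list(corr_tables[ds].table["gene"])
        per_ds_genes.append(set(genes))
        for g in genes:
            if g not in seen:
                seen.add(g)
                universe.append(g)
    common = set.intersection(*per_ds_genes)

    idx = pd.Index(universe, name="gene")
    n_ds = len(datasets)
    r_mat = pd.DataFrame(np.nan, index=idx, columns=datasets)
    padj_mat = pd.DataFrame(np.nan, index=idx, columns=datasets)
    sign_mat = pd.DataFrame(0, index=idx, columns=datasets, dtype=int)
    for ds in datasets:
        ct = corr_tables[ds].table.set_index("gene")
        ok = ct.index[ct["defined"]]
        r_mat.loc[ok, ds] = ct.loc[ok, "r"]
        de = de_tables.get(ds)
        if de is None:
            continue
        de = de.set_index("gene") if "gene" in de.columns else de
        hit = de.index.intersection(idx)
        padj_mat.loc[hit, ds] = de.loc[hit, "padj"].to_numpy()
        if "log2fc" in de.columns:
            s = np.sign(de.loc[hit, "log2fc"].to_numpy())
            sign_mat.loc[hit, ds] = np.where(np.isfinite(s), s, 0).astype(int)

    r_pass = (r_mat.abs() >= r_min)
    n_r_pass = r_pass.sum(axis=1).astype(int)
    de_pass = (padj_mat <= padj_max)
    n_de_pass = de_pass.sum(axis=1).astype(int)
    if de_rule == "all_datasets":
        de_ok = n_de_pass == n_ds
    else:
        de_ok = n_de_pass >= min_datasets_r
    passed = (n_r_pass >= min_datasets_r) & de_ok

    signs = np.sign(r_mat.where(r_pass).to_numpy())
    any_pos = np.nansum(signs > 0, axis=1) > 0
    any_neg = np.nansum(signs < 0, axis=1) > 0
    direction = np.where(
        any_pos & any_neg, "mixed",
        np.where(any_neg, "negative", np.where(any_pos, "positive", "none")),
    )

    table = pd.DataFrame({"gene": universe})
    for ds in datasets:
        table[f"r_{ds}"] = r_mat[ds].to_numpy()
        table[f"padj_{ds}"] = padj_mat[ds].to_numpy()
        table[f"de_sign_{ds}"] = sign_mat[ds].to_numpy()
    table["mean_r"] = r_mat.mean(axis=1).to_numpy()
    table["n_r_pass"] = n_r_pass.to_numpy()
    table["n_de_pass"] = n_de_pass.to_numpy()
    table["pass"] = passed.to_numpy()
    table["direction"] = direction

    return ConsensusTable(
        anchor=anchor,
        table=table,
        thresholds={
            "r_min": r_min, "min_datasets_r": min_datasets_r,
            "padj_max": padj_max, "de_rule": de_rule, "n_datasets": n_ds,
        },
        n_genes_common=len(common),
    )
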