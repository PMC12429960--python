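"""Synthetic bulk time courses and annotated single-cell matrices with known
ground truth, so every stage of the screen is testable without downloads.

Bulk generator
--------------
Gene mean trajectories are specified on the log2(CPM+4) scale — the scale the
screen correlates on — and inverted to count space, so planted correlations
are controlled directly. The anchor follows a step trajectory with a known
drop; planted genes track the anchor (slope ``corr_slope``, sign +/-) plus a
smooth AR(1) deviation whose stationary spread is derived from the target
planted correlation ``planted_abs_corr``; null genes are flat apart from
their own smooth AR(1) wander. Counts are negative binomial around
per-sample expected counts with lognormal library sizes. Trajectory-level
deviations are autocorrelated (AR(1)) rather than independent per timepoint
because biological drift across adjacent developmental ages is smooth;
independent jitter would also make transition fold changes far noisier than
the trajectories themselves.

Single-cell generator
---------------------
Cells get a type and a postnatal stage by stated proportions. Gene A is
expressed (probabilistically) in its types, gene B in its own, with exactly
one shared type; within the shared type, a cell expressing A also expresses
B with probability ``exclusivity`` (0 = perfectly mutually exclusive).
Expressed entries get lognormal positive normalized values. The generator
returns the realized co-expression counts as exact ground truth.

All generators are fully deterministic under their seed; per-dataset
sub-streams derive from the master seed via ``numpy.random.SeedSequence``
spawn keys, which is stable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import AnchorscreenError, CellMatrix, CountMatrix
from .sc_coexpr import CoexpressionCounts

LOG2CPM4_FLOOR = 2.0  # log2(0 + 4)
CPM_FLOOR = 0.1  # expected-CPM clip when inverting the log scale


# ---------------------------------------------------------------------------
# Bulk
# ---------------------------------------------------------------------------


@dataclass
class BulkSimConfig:
    """Study conditions for one synthetic bulk developmental time course.

    Defaults emulate a 4-timepoint, 4-replicate developmental dataset whose
    anchor gene drops 4-fold at the third timepoint, with 50 positively and
    50 negatively tracking genes planted at target |r| ~ 0.9 among 2000
    genes, NB dispersion 0.1 and ~1e7-read libraries.
    """

    n_genes: int = 2000
    timepoint_labels: tuple[str, ...] = ("P0", "P7", "P14", "P28")
    n_replicates: int = 4
    anchor_name: str = "Mkrn3"
    anchor_level: float = 10.0  # log2(CPM+4) before the drop
    drop_factor: float = 4.0  # fold drop, applied as -log2(drop_factor)
    drop_index: int = 2  # first timepoint at the lower level
    anchor_trajectory: tuple[float, ...] | None = None  # overrides the step
    n_pos_corr: int = 50
    n_neg_corr: int = 50
    corr_slope: float = 1.0
    planted_abs_corr: float = 0.9  # target |r| of planted genes vs anchor
    traj_noise_ar: float = 0.7  # lag-1 autocorrelation of trajectory noise
    planted_level_mean: float = 8.0
    planted_level_sd: float = 1.0
    null_level_mean: float = 6.0
    null_level_sd: float = 2.0
    null_traj_sd: float = 0.3
    dispersion: float = 0.1
    libsize_median: float = 1e7
    libsize_lognorm_sd: float = 0.2
    seed: int = 0

    @property
    def n_timepoints(self) -> int:
        return len(self.anchor_traj())

    def anchor_traj(self) -> np.ndarray:
        if self.anchor_trajectory is not None:
            return np.asarray(self.anchor_trajectory, dtype=float)
        T = len(self.timepoint_labels)
        traj = np.full(T, self.anchor_level)
        traj[self.drop_index:] -= np.log2(self.drop_factor)
        return traj

    def planted_noise_sd(self) -> float:
        """Stationary sd of planted-gene trajectory noise implied by the
        target planted correlation.

        Pearson r over the T timepoints compares the centered anchor signal
        (variance sd_A^2) with the centered noise. For stationary AR(1)
        noise of marginal variance sd^2 and correlation matrix R, centering
        removes the (large, shared) offset component, leaving an effective
        per-point variance of sd^2 * f with f = tr(C R C) / T, C = I - J/T.
        Solving rho = b sd_A / sqrt(b^2 sd_A^2 + sd^2 f) for sd gives the
        calibration.
        """
        T = self.n_timepoints
        sd_a = float(self.anchor_traj().std())
        rho = self.planted_abs_corr
        R = self.traj_noise_ar ** np.abs(np.subtract.outer(np.arange(T),
                                                           np.arange(T)))
        C = np.eye(T) - np.full((T, T), 1.0 / T)
        f = float(np.trace(C @ R @ C)) / T
        target_centered_var = (abs(self.corr_slope) * sd_a) ** 2 * (1.0 / rho**2 - 1.0)
        return float(np.sqrt(target_centered_var / f))

    def validate(self) -> None:
        T = len(self.timepoint_labels)
        if T < 2:
            raise AnchorscreenError("need at least 2 timepoints")
        if self.anchor_trajectory is not None and len(self.anchor_trajectory) != T:
            raise AnchorscreenError("anchor_trajectory length must match timepoints")
        if not (1 <= self.drop_index <= T - 1):
            raise AnchorscreenError(f"drop_index must lie in [1, {T - 1}]")
        if self.n_replicates < 2:
            raise AnchorscreenError("need >= 2 replicates per timepoint")
        if self.dispersion < 0:
            raise AnchorscreenError("dispersion must be >= 0")
        if not (0 < self.planted_abs_corr < 1):
            raise AnchorscreenError("planted_abs_corr must lie in (0, 1)")
        if not (0 <= self.traj_noise_ar < 1):
            raise AnchorscreenError("traj_noise_ar must lie in [0, 1)")
        if self.n_pos_corr + self.n_neg_corr + 1 > self.n_genes:
            raise AnchorscreenError("planted genes + anchor exceed n_genes")
        if self.drop_factor <= 0 or self.libsize_median <= 0:
            raise AnchorscreenError("drop_factor and libsize_median must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated dataset: per-gene role
    (anchor / pos_corr / neg_corr / null), sign, realized trajectory-level
    correlation with the anchor, and the true trajectories themselves."""

    table: pd.DataFrame  # columns: gene, role, true_sign, true_r
    true_trajectories: np.ndarray  # genes x timepoints, log2(CPM+4) means
    drop_index: int
    dataset_id: str
    seed: int

    def genes_with_role(self, role: str) -> list[str]:
        t = self.table
        return list(t.loc[t["role"] == role, "gene"])


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               sd: float, ar: float) -> np.ndarray:
    """Stationary AR(1) rows: smooth trajectory-level deviations."""
    n, T = shape
    out = np.empty(shape)
    out[:, 0] = rng.normal(0.0, sd, size=n)
    innov_sd = sd * np.sqrt(1.0 - ar**2)
    for t in range(1, T):
        out[:, t] = ar * out[:, t - 1] + rng.normal(0.0, innov_sd, size=n)
    return out


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi < 1e-12:
        return rng.poisson(mu)
    n = 1.0 / phi
    p = 1.0 / (1.0 + phi * mu)
    return rng.negative_binomial(n, p)


def _gene_names(config: BulkSimConfig) -> tuple[list[str], list[str], np.ndarray]:
    """Deterministic gene naming and role assignment shared across datasets."""
    n_null = config.n_genes - 1 - config.n_pos_corr - config.n_neg_corr
    names = [config.anchor_name]
    roles = ["anchor"]
    signs = [1]
    for i in range(config.n_pos_corr):
        names.append(f"POS{i + 1:04d}")
        roles.append("pos_corr")
        signs.append(1)
    for i in range(config.n_neg_corr):
        names.append(f"NEG{i + 1:04d}")
        roles.append("neg_corr")
        signs.append(-1)
    for i in range(n_null):
        names.append(f"NULL{i + 1:05d}")
        roles.append("null")
        signs.append(0)
    return names, roles, np.array(signs)


def simulate_bulk(
    config: BulkSimConfig,
    dataset_id: str = "DS1",
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate one bulk dataset and its ground truth."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = config.n_timepoints
    anchor = config.anchor_traj()
    names, roles, signs = _gene_names(config)
    n = config.n_genes

    M = np.empty((n, T))
    M[0] = anchor
    n_planted = config.n_pos_corr + config.n_neg_corr
    if n_planted:
        sl = slice(1, 1 + n_planted)
        offsets = rng.normal(config.planted_level_mean, config.planted_level_sd,
                             size=n_planted)
        centered = anchor - anchor.mean()
        noise = _ar1_noise(rng, (n_planted, T), config.planted_noise_sd(),
                           config.traj_noise_ar)
        M[sl] = (offsets[:, None]
                 + signs[sl, None] * config.corr_slope * centered[None, :]
                 + noise)
    n_null = n - 1 - n_planted
    if n_null:
        levels = rng.normal(config.null_level_mean, config.null_level_sd, size=n_null)
        levels = np.maximum(levels, LOG2CPM4_FLOOR)
        M[1 + n_planted:] = levels[:, None] + _ar1_noise(
            rng, (n_null, T), config.null_traj_sd, config.traj_noise_ar)
    M = np.maximum(M, LOG2CPM4_FLOOR)

    # realized trajectory-level correlation with the anchor (exact truth)
    Ac = anchor - anchor.mean()
    Xc = M - M.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.einsum("ij,ij->i", Xc, Xc) * (Ac @ Ac))
    with np.errstate(invalid="ignore", divide="ignore"):
        true_r = np.where(denom > 0, (Xc @ Ac) / denom, np.nan)

    n_samples = T * config.n_replicates
    libsizes = rng.lognormal(np.log(config.libsize_median),
                             config.libsize_lognorm_sd, size=n_samples)
    tp_of_sample = np.repeat(np.arange(T), config.n_replicates)
    target_cpm = np.maximum(np.exp2(M) - 4.0, CPM_FLOOR)
    mu = target_cpm[:, tp_of_sample] * (libsizes / 1e6)[None, :]
    counts = _nb_counts(rng, mu, config.dispersion)

    sample_ids = [
        f"{dataset_id}_T{t}_R{r + 1}"
        for t in range(T) for r in range(config.n_replicates)
    ]
    meta = pd.DataFrame({
        "dataset": dataset_id,
        "timepoint": tp_of_sample,
        "timepoint_label": [config.timepoint_labels[t] for t in tp_of_sample],
        "replicate": [f"R{r + 1}" for _ in range(T) for r in range(config.n_replicates)],
    }, index=pd.Index(sample_ids, name="sample"))

    cm = CountMatrix(gene_ids=names, sample_ids=sample_ids,
                     counts=counts.astype(np.int64), sample_meta=meta)
    truth = SyntheticTruth(
        table=pd.DataFrame({
            "gene": names, "role": roles, "true_sign": signs, "true_r": true_r,
        }),
        true_trajectories=M,
        drop_index=config.drop_index,
        dataset_id=dataset_id,
        seed=config.seed,
    )
    return cm, truth


def simulate_multidataset(
    config: BulkSimConfig,
    n_datasets: int = 5,
    dataset_noise_sd: float = 0.25,
) -> list[tuple[CountMatrix, SyntheticTruth]]:
    """Simulate several datasets sharing planted roles, signs and drop index.

    Each dataset gets an independent sub-stream (SeedSequence spawn key =
    dataset index), independent trajectory noise, offsets and library sizes,
    plus a per-gene constant baseline shift of sd ``dataset_noise_sd`` so
    datasets are not mere replicates of each other. Constant shifts leave
    correlations and fold changes untouched.
    """
    if n_datasets < 1:
        raise AnchorscreenError("n_datasets must be >= 1")
    config.validate()
    out = []
    for i in range(n_datasets):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(i,)))
        dataset_id = f"DS{i + 1}"
        cm, truth = simulate_bulk(config, dataset_id=dataset_id, rng=rng)
        if dataset_noise_sd > 0:
            # re-simulate counts with shifted baselines, keeping trajectories'
            # shape: a constant per-gene shift on the log2 scale
            shift = rng.normal(0.0, dataset_noise_sd, size=config.n_genes)
            shift[0] = 0.0  # anchor trajectory identical across datasets
            M = np.maximum(truth.true_trajectories + shift[:, None], LOG2CPM4_FLOOR)
            T = config.n_timepoints
            n_samples = T * config.n_replicates
            libsizes = rng.lognormal(np.log(config.libsize_median),
                                     config.libsize_lognorm_sd, size=n_samples)
            tp = np.repeat(np.arange(T), config.n_replicates)
            mu = np.maximum(np.exp2(M) - 4.0, CPM_FLOOR)[:, tp] * (libsizes / 1e6)
            cm = CountMatrix(
                gene_ids=list(cm.gene_ids), sample_ids=list(cm.sample_ids),
                counts=_nb_counts(rng, mu, config.dispersion).astype(np.int64),
                sample_meta=cm.sample_meta,
            )
            truth.true_trajectories = M
            # clipping at the floor can nudge low trajectories: refresh true_r
            anchor_traj = M[0]
            Ac = anchor_traj - anchor_traj.mean()
            Xc = M - M.mean(axis=1, keepdims=True)
            denom = np.sqrt(np.einsum("ij,ij->i", Xc, Xc) * (Ac @ Ac))
            with np.errstate(invalid="ignore", divide="ignore"):
                truth.table["true_r"] = np.where(denom > 0, (Xc @ Ac) / denom, np.nan)
        out.append((cm, truth))
    return out


# ---------------------------------------------------------------------------
# Single cell
# ---------------------------------------------------------------------------


@dataclass
class CellTypeProfile:
    """Per-type proportions and expression probabilities of the two genes."""

    proportion: float
    p_a: float
    p_b: float


def _default_cell_types() -> dict[str, CellTypeProfile]:
    # emulates a hypothalamic census: gene A in oligodendrocyte/tanycyte/
    # neuron-like types, gene B in neuron/astrocyte-like types; the neurons
    # are the only type where both can appear
    return {
        "Neuron": CellTypeProfile(0.45, p_a=0.06, p_b=0.07),
        "Oligodendrocyte": CellTypeProfile(0.20, p_a=0.15, p_b=0.0),
        "Tanycyte": CellTypeProfile(0.10, p_a=0.12, p_b=0.0),
        "Astrocyte": CellTypeProfile(0.15, p_a=0.0, p_b=0.10),
        "Microglia": CellTypeProfile(0.10, p_a=0.0, p_b=0.0),
    }


@dataclass
class ScSimConfig:
    """Study conditions for the synthetic single-cell matrix."""

    n_cells: int = 3000
    gene_a: str = "Mkrn3"
    gene_b: str = "Acvr1c"
    n_background_genes: int = 20
    cell_types: dict[str, CellTypeProfile] = field(default_factory=_default_cell_types)
    shared_type: str = "Neuron"
    exclusivity: float = 0.01  # P(cell expresses B | it expresses A), shared type
    stages: dict[str, float] = field(default_factory=lambda: {
        "P4": 0.25, "P8": 0.25, "P14": 0.25, "P45": 0.25,
    })
    expr_mean: float = 1.0  # scale of lognormal normalized values
    dropout_rate: float = 0.0  # extra thinning of expressed entries
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise AnchorscreenError("n_cells must be >= 1")
        for name, probs in (("cell_types", {k: v.proportion for k, v in self.cell_types.items()}),
                            ("stages", self.stages)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise AnchorscreenError(f"{name} proportions sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise AnchorscreenError(f"{name} proportions must be >= 0")
        for t, prof in self.cell_types.items():
            if not (0 <= prof.p_a <= 1 and 0 <= prof.p_b <= 1):
                raise AnchorscreenError(f"expression probabilities of {t} outside [0,1]")
        if not 0 <= self.exclusivity <= 1:
            raise AnchorscreenError("exclusivity must lie in [0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise AnchorscreenError("dropout_rate must lie in [0, 1)")
        if self.shared_type not in self.cell_types:
            raise AnchorscreenError(f"shared_type {self.shared_type!r} not in cell_types")


def simulate_sc(config: ScSimConfig) -> tuple[CellMatrix, CoexpressionCounts]:
    """Simulate an annotated single-cell matrix plus realized truth counts.

    The returned :class:`CoexpressionCounts` is the exact per-cell
    classification of the generated matrix within the shared type, so
    analyzer output must match it identically.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = list(config.cell_types)
    type_p = np.array([config.cell_types[t].proportion for t in types])
    stage_names = list(config.stages)
    stage_p = np.array([config.stages[s] for s in stage_names])

    cell_type = rng.choice(types, size=config.n_cells, p=type_p / type_p.sum())
    stage = rng.choice(stage_names, size=config.n_cells, p=stage_p / stage_p.sum())

    p_a = np.array([config.cell_types[t].p_a for t in cell_type])
    p_b = np.array([config.cell_types[t].p_b for t in cell_type])
    expr_a = rng.random(config.n_cells) < p_a
    shared = cell_type == config.shared_type
    expr_b = rng.random(config.n_cells) < p_b
    # within the shared type, B is tied to A by the exclusivity parameter
    tied = shared & expr_a
    expr_b[tied] = rng.random(int(tied.sum())) < config.exclusivity

    if config.dropout_rate > 0:
        expr_a &= rng.random(config.n_cells) >= config.dropout_rate
        expr_b &= rng.random(config.n_cells) >= config.dropout_rate

    n_bg = config.n_background_genes
    gene_ids = [config.gene_a, config.gene_b] + [f"BG{i + 1:03d}" for i in range(n_bg)]
    dense = np.zeros((config.n_cells, 2 + n_bg))

    def values(mask: np.ndarray) -> np.ndarray:
        k = int(mask.sum())
        return rng.lognormal(np.log(config.expr_mean), 0.5, size=k)

    dense[expr_a, 0] = values(expr_a)
    dense[expr_b, 1] = values(expr_b)
    if n_bg:
        bg_p = rng.uniform(0.05, 0.3, size=n_bg)
        for j in range(n_bg):
            mask = rng.random(config.n_cells) < bg_p[j]
            if config.dropout_rate > 0:
                mask &= rng.random(config.n_cells) >= config.dropout_rate
            dense[mask, 2 + j] = values(mask)

    cell_ids = [f"CELL{i + 1:06d}" for i in range(config.n_cells)]
    cells = CellMatrix(
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        expr=sp.csr_matrix(dense),
        cell_meta=pd.DataFrame(
            {"cell_type": cell_type, "stage": stage},
            index=pd.Index(cell_ids, name="barcode"),
        ),
    )

    # realized truth within the shared type, per stage
    a_s, b_s, st_s = expr_a[shared], expr_b[shared], stage[shared]

    def tally(a: np.ndarray, b: np.ndarray) -> dict[str, int]:
        both = int((a & b).sum())
        ao = int((a & ~b).sum())
        bo = int((~a & b).sum())
        return {"n_total": ao + bo + both, "n_a_only": ao, "n_b_only": bo,
                "n_both": both}

    breakdown = {str(s): tally(a_s[st_s == s], b_s[st_s == s])
                 for s in pd.unique(st_s)}
    truth = CoexpressionCounts(
        gene_a=config.gene_a, gene_b=config.gene_b,
        cell_type=config.shared_type, threshold=0.0,
        stage_breakdown=breakdown, **tally(a_s, b_s),
    )
    return cells, truth
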