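import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import anchorscreen as a
from anchorscreen import AnchorscreenError
from anchorscreen.bulk_screen import exact_rank_sum, exact_signed_rank, min_attainable_p


def pearson_oracle(x, y):
    """Direct textbook formula, independent of the vectorized path."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)


class TestNormalization:
    def test_cpm_proportions(self, tiny_counts):
        norm = a.cpm(tiny_counts)
        col = tiny_counts.counts[:, 0] / tiny_counts.counts[:, 0].sum() * 1e6
        np.testing.assert_allclose(norm.values[:, 0], col)

    def test_cpm_single_sample_example(self):
        meta = pd.DataFrame({"dataset": "D", "timepoint": [0],
                             "timepoint_label": ["t0"], "replicate": ["r1"]},
                            index=pd.Index(["s1"], name="sample"))
        cm = a.CountMatrix(["g1", "g2", "g3"], ["s1"],
                           np.array([[1], [1], [2]]), meta)
        np.testing.assert_allclose(a.cpm(cm).values.ravel(),
                                   [250000, 250000, 500000])

    def test_cpm_scale_invariance(self, tiny_counts):
        doubled = a.CountMatrix(tiny_counts.gene_ids, tiny_counts.sample_ids,
                                tiny_counts.counts * 10, tiny_counts.sample_meta)
        np.testing.assert_allclose(a.cpm(doubled).values, a.cpm(tiny_counts).values)

    def test_cpm_rejects_zero_sample(self, tiny_counts):
        counts = tiny_counts.counts.copy()
        counts[:, 2] = 0
        cm = a.CountMatrix(tiny_counts.gene_ids, tiny_counts.sample_ids, counts,
                           tiny_counts.sample_meta)
        with pytest.raises(AnchorscreenError, match="S2"):
            a.cpm(cm)

    def test_cpm_column_sums_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n_g, n_s = rng.integers(2, 40), rng.integers(1, 8)
            counts = rng.integers(0, 1000, size=(n_g, n_s))
            counts[0] += 1  # no all-zero sample
            meta = pd.DataFrame({
                "dataset": "D", "timepoint": 0, "timepoint_label": "t",
                "replicate": [f"r{i}" for i in range(n_s)],
            }, index=pd.Index([f"s{i}" for i in range(n_s)], name="sample"))
            cm = a.CountMatrix([f"g{i}" for i in range(n_g)],
                               [f"s{i}" for i in range(n_s)], counts, meta)
            sums = a.cpm(cm).values.sum(axis=0)
            np.testing.assert_allclose(sums, 1e6, rtol=1e-6)

    @pytest.mark.parametrize("cpm_value,expected", [
        (0.0, 2.0), (4.0, 3.0), (1e6, math.log2(1000004.0)),
    ])
    def test_log2cpm4_values(self, cpm_value, expected):
        meta = pd.DataFrame({"dataset": "D", "timepoint": [0],
                             "timepoint_label": ["t"], "replicate": ["r"]},
                            index=pd.Index(["s"], name="sample"))
        norm = a.NormalizedMatrix(["g"], ["s"], np.array([[cpm_value]]),
                                  "CPM", meta)
        assert a.log2cpm4(norm).values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_log2cpm4_requires_cpm_input(self, tiny_counts):
        norm = a.log2cpm4(a.cpm(tiny_counts))
        with pytest.raises(AnchorscreenError, match="CPM"):
            a.log2cpm4(norm)


class TestTimepointMeans:
    def test_means_match_brute_force(self, small_bulk):
        _, cm, _ = small_bulk
        norm = a.log2cpm4(a.cpm(cm))
        prof = a.timepoint_means(norm)
        meta = norm.sample_meta
        for t in sorted(meta["timepoint"].unique()):
            idx = [norm.sample_ids.index(s)
                   for s in meta.index[meta["timepoint"] == t]]
            expected = norm.values[:, idx].mean(axis=1)
            np.testing.assert_allclose(prof.timepoint_means[:, t], expected,
                                       atol=1e-12)

    def test_single_replicate_is_identity(self, tiny_counts):
        one = tiny_counts.subset_samples(["S0", "S2", "S4"])
        norm = a.log2cpm4(a.cpm(one))
        prof = a.timepoint_means(norm)
        np.testing.assert_allclose(prof.timepoint_means, norm.values)

    def test_pair_average(self, tiny_counts):
        norm = a.log2cpm4(a.cpm(tiny_counts))
        prof = a.timepoint_means(norm)
        gi = 0
        assert prof.timepoint_means[gi, 0] == pytest.approx(
            (norm.values[gi, 0] + norm.values[gi, 1]) / 2)


class TestExactWilcoxon:
    def test_signed_rank_min_p_four_pairs(self):
        # enumeration over 2^4 sign patterns: most extreme outcome has
        # probability 1/16 per tail, so the smallest two-sided p is 0.125
        assert min_attainable_p("signed_rank", 4) == pytest.approx(0.125)

    def test_rank_sum_complete_separation_six_vs_six(self):
        x = np.arange(6.0)
        _, p = exact_rank_sum(x, x + 100.0)
        assert p == pytest.approx(2 / math.comb(12, 6))

    @pytest.mark.parametrize("n,m", [(4, 4), (5, 7), (8, 8)])
    def test_rank_sum_matches_scipy_exact_without_ties(self, n, m):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x, y = rng.normal(size=n), rng.normal(size=m)
            _, p = exact_rank_sum(x, y)
            ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                           method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 6, 10])
    def test_signed_rank_matches_scipy_exact_without_ties(self, n):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x, y = rng.normal(size=n), rng.normal(size=n)
            _, p = exact_signed_rank(x, y)
            ref = scipy.stats.wilcoxon(x, y, alternative="two-sided",
                                       method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_ties_handled_with_exact_enumeration(self):
        # tied data keep a valid exact p (scipy falls back to approximation)
        x = np.array([1.0, 1.0, 2.0, 3.0])
        y = np.array([4.0, 4.0, 5.0, 6.0])
        _, p = exact_rank_sum(x, y)
        assert p == pytest.approx(2 / math.comb(8, 4))

    def test_all_zero_differences_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        _, p = exact_signed_rank(x, x)
        assert p == 1.0


class TestDetectDrop:
    def _norm(self, groups, replicates=None):
        """Build a LOG2CPM4 NormalizedMatrix with given anchor group values."""
        values = np.concatenate(groups)
        n_per = [len(g) for g in groups]
        samples = [f"s{i}" for i in range(len(values))]
        reps = replicates or sum(([f"r{j}" for j in range(k)] for k in n_per), [])
        meta = pd.DataFrame({
            "dataset": "D",
            "timepoint": np.repeat(np.arange(len(groups)), n_per),
            "timepoint_label": [f"t{t}" for t in np.repeat(np.arange(len(groups)), n_per)],
            "replicate": reps,
        }, index=pd.Index(samples, name="sample"))
        mat = np.vstack([values, np.linspace(5, 6, len(values))])
        return a.NormalizedMatrix(["ANCHOR", "OTHER"], samples, mat,
                                  "LOG2CPM4", meta)

    def test_step_drop_found_with_six_replicates(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(10, 0.1, 6), rng.normal(10, 0.1, 6),
                  rng.normal(6, 0.1, 6), rng.normal(6, 0.1, 6)]
        res = a.detect_drop(self._norm(groups), "ANCHOR", test="rank_sum")
        assert res.drop_index == 2
        assert res.transitions[1].p == pytest.approx(2 / math.comb(12, 6))
        assert res.transitions[1].direction == "decrease"

    def test_constant_anchor_yields_no_drop(self):
        groups = [np.full(4, 5.0)] * 3
        res = a.detect_drop(self._norm(groups), "ANCHOR", test="rank_sum")
        assert res.drop_index is None
        assert not res.anova_defined

    def test_increase_direction_flag(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(6, 0.05, 6), rng.normal(10, 0.05, 6)]
        res = a.detect_drop(self._norm(groups), "ANCHOR", test="rank_sum",
                            direction="increase")
        assert res.drop_index == 1
        down = a.detect_drop(self._norm(groups), "ANCHOR", test="rank_sum")
        assert down.drop_index is None

    def test_rank_sum_invariant_to_replicate_order(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(10, 0.5, 5), rng.normal(8, 0.5, 5)]
        res1 = a.detect_drop(self._norm(groups), "ANCHOR", test="rank_sum")
        shuffled = [g[::-1].copy() for g in groups]
        res2 = a.detect_drop(self._norm(shuffled), "ANCHOR", test="rank_sum")
        assert [t.p for t in res1.transitions] == [t.p for t in res2.transitions]

    def test_signed_rank_refuses_mismatched_replicate_labels(self):
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0])]
        norm = self._norm(groups, replicates=["r0", "r1", "r2", "r3"])
        with pytest.raises(AnchorscreenError, match="rank_sum"):
            a.detect_drop(norm, "ANCHOR", test="signed_rank")

    def test_signed_rank_invariant_to_consistent_pair_relabeling(self):
        rng = np.random.default_rng(6)
        vals = [rng.normal(10, 0.5, 4), rng.normal(8, 0.5, 4)]
        norm1 = self._norm(vals, replicates=["r0", "r1", "r2", "r3"] * 2)
        res1 = a.detect_drop(norm1, "ANCHOR", test="signed_rank", alpha=0.2)
        # swap pair labels r0<->r3, r1<->r2 in both timepoints consistently
        relabeled = ["r3", "r2", "r1", "r0"] * 2
        norm2 = self._norm(vals, replicates=relabeled)
        res2 = a.detect_drop(norm2, "ANCHOR", test="signed_rank", alpha=0.2)
        assert [t.p for t in res1.transitions] == [t.p for t in res2.transitions]

    def test_missing_anchor_raises(self, tiny_counts):
        norm = a.log2cpm4(a.cpm(tiny_counts))
        with pytest.raises(KeyError):
            a.detect_drop(norm, "NOSUCH", test="rank_sum")

    def test_reported_min_attainable_p(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(10, 0.5, 4), rng.normal(8, 0.5, 4)]
        res = a.detect_drop(self._norm(groups), "ANCHOR", test="signed_rank")
        assert res.transitions[0].min_p == pytest.approx(0.125)


class TestCorrelateWithAnchor:
    def _profile(self, means, genes):
        return a.TimepointProfile(gene_ids=genes, dataset_id="D",
                                  timepoint_means=np.asarray(means, float),
                                  timepoint_labels=[f"t{i}" for i in
                                                    range(np.asarray(means).shape[1])])

    def test_worked_example(self):
        prof = self._profile([[1, 2, 3, 4], [1, 3, 2, 4]], ["A", "G"])
        table = a.correlate_with_anchor(prof, "A").table.set_index("gene")
        assert table.loc["G", "r"] == pytest.approx(0.8)
        assert table.loc["A", "r"] == 1.0

    def test_anticorrelated_gene(self):
        prof = self._profile([[1, 2, 3, 4], [9, 8, 7, 6]], ["A", "G"])
        table = a.correlate_with_anchor(prof, "A").table.set_index("gene")
        assert table.loc["G", "r"] == pytest.approx(-1.0)

    def test_zero_variance_gene_flagged_undefined(self):
        prof = self._profile([[1, 2, 3], [5, 5, 5]], ["A", "G"])
        table = a.correlate_with_anchor(prof, "A").table.set_index("gene")
        assert not table.loc["G", "defined"]
        assert np.isnan(table.loc["G", "r"])

    def test_requires_three_timepoints(self):
        prof = self._profile([[1, 2], [3, 4]], ["A", "G"])
        with pytest.raises(AnchorscreenError, match="3"):
            a.correlate_with_anchor(prof, "A")

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(8)
        means = rng.normal(size=(400, 8))
        genes = [f"g{i}" for i in range(400)]
        table = a.correlate_with_anchor(self._profile(means, genes), "g0").table
        for i in rng.choice(400, size=60, replace=False):
            if i == 0:
                continue
            expected = pearson_oracle(list(means[0]), list(means[i]))
            assert table["r"].iloc[i] == pytest.approx(expected, abs=1e-10)


def brute_force_consensus(r_by_gene, padj_by_gene, r_min, min_datasets_r,
                          padj_max, de_rule, n_datasets):
    """Independent re-evaluation of the consensus rule with plain loops."""
    out = {}
    for gene in r_by_gene:
        n_r = sum(1 for r in r_by_gene[gene]
                  if r is not None and abs(r) >= r_min)
        n_de = sum(1 for p in padj_by_gene[gene]
                   if p is not None and p <= padj_max)
        if de_rule == "all_datasets":
            de_ok = n_de == n_datasets
        else:
            de_ok = n_de >= min_datasets_r
        out[gene] = (n_r >= min_datasets_r) and de_ok
    return out


class TestConsensusFilter:
    def _tables(self, rng, n_genes=100, n_ds=5):
        genes = [f"g{i}" for i in range(n_genes)]
        corr, de = {}, {}
        r_by_gene = {g: [] for g in genes}
        padj_by_gene = {g: [] for g in genes}
        for d in range(n_ds):
            ds = f"DS{d}"
            r = np.round(rng.uniform(-1, 1, n_genes), 3)
            padj = np.round(rng.uniform(0, 0.2, n_genes), 4)
            corr[ds] = a.CorrelationTable(ds, "g0", pd.DataFrame({
                "gene": genes, "r": r, "n_timepoints": 4, "defined": True,
            }))
            de[ds] = pd.DataFrame({"gene": genes, "padj": padj,
                                   "log2fc": rng.normal(size=n_genes)})
            for g, rv, pv in zip(genes, r, padj):
                r_by_gene[g].append(rv)
                padj_by_gene[g].append(pv)
        return corr, de, r_by_gene, padj_by_gene

    @pytest.mark.parametrize("de_rule", ["all_datasets", "min_datasets"])
    def test_pass_set_matches_brute_force(self, de_rule):
        rng = np.random.default_rng(9)
        corr, de, r_by_gene, padj_by_gene = self._tables(rng)
        cons = a.consensus_filter(corr, de, de_rule=de_rule)
        expected = brute_force_consensus(r_by_gene, padj_by_gene, 0.6, 3, 0.05,
                                         de_rule, 5)
        got = dict(zip(cons.table["gene"], cons.table["pass"]))
        assert got == expected

    def test_default_thresholds_negative_gene_passes(self):
        genes = ["G"]
        corr, de = {}, {}
        rs = [-0.9, -0.9, -0.9, 0.1, 0.2]
        for i, r in enumerate(rs):
            ds = f"DS{i}"
            corr[ds] = a.CorrelationTable(ds, "A", pd.DataFrame(
                {"gene": genes, "r": [r], "n_timepoints": 4, "defined": True}))
            de[ds] = pd.DataFrame({"gene": genes, "padj": [0.01], "log2fc": [1.0]})
        cons = a.consensus_filter(corr, de, de_rule="all_datasets")
        row = cons.table.iloc[0]
        assert row["pass"]
        assert row["direction"] == "negative"

    def test_boundary_r_point_59_fails(self):
        genes = ["G"]
        corr = {f"DS{i}": a.CorrelationTable(f"DS{i}", "A", pd.DataFrame(
            {"gene": genes, "r": [0.59], "n_timepoints": 4, "defined": True}))
            for i in range(5)}
        de = {ds: pd.DataFrame({"gene": genes, "padj": [0.001], "log2fc": [1.0]})
              for ds in corr}
        cons = a.consensus_filter(corr, de)
        assert not cons.table["pass"].iloc[0]
        assert cons.table["n_r_pass"].iloc[0] == 0

    def test_gene_absent_from_a_dataset_counts_as_fail_there(self):
        corr = {}
        de = {}
        for i in range(3):
            ds = f"DS{i}"
            genes = ["G", "H"] if i < 2 else ["G"]
            corr[ds] = a.CorrelationTable(ds, "A", pd.DataFrame(
                {"gene": genes, "r": 0.9, "n_timepoints": 4, "defined": True}))
            de[ds] = pd.DataFrame({"gene": genes, "padj": 0.01, "log2fc": 1.0})
        cons = a.consensus_filter(corr, de, min_datasets_r=3,
                                  de_rule="all_datasets")
        t = cons.table.set_index("gene")
        assert t.loc["G", "pass"]
        assert not t.loc["H", "pass"]
        assert t.loc["H", "n_r_pass"] == 2

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(10)
        corr, de, *_ = self._tables(rng)
        base = set(a.consensus_filter(corr, de).table.query("`pass`")["gene"])
        stricter_r = set(a.consensus_filter(corr, de, r_min=0.8)
                         .table.query("`pass`")["gene"])
        stricter_p = set(a.consensus_filter(corr, de, padj_max=0.01)
                         .table.query("`pass`")["gene"])
        assert stricter_r <= base
        assert stricter_p <= base

    def test_empty_dataset_list_rejected(self):
        with pytest.raises(AnchorscreenError):
            a.consensus_filter({}, {})


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-50, 50), min_size=3, max_size=10),
       st.floats(-5, 5), st.floats(0.1, 5))
def test_correlation_affine_invariance(values, shift, scale):
    """r(anchor, a + b*anchor) = sign(b) when the anchor varies."""
    arr = np.asarray(values)
    if np.ptp(arr) < 1e-6 or not np.isfinite(arr).all():
        return
    means = np.vstack([arr, shift + scale * arr])
    prof = a.TimepointProfile(["A", "G"], "D", means,
                              [f"t{i}" for i in range(len(values))])
    table = a.correlate_with_anchor(prof, "A").table
    assert table["r"].iloc[1] == pytest.approx(1.0, abs=1e-9)
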