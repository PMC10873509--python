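"""Clustering, concordance, overlap enrichment and KS comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import mpramix as mx
from mpramix.counts import ActivityMatrix
from mpramix.downstream import ecdf_summary, sign_concordance


def _am_from_matrix(mat: pd.DataFrame, tps=None) -> ActivityMatrix:
    samples = pd.DataFrame(
        {"time_point": tps or ["iPSC"] * mat.shape[1]},
        index=mat.columns,
    )
    tpm = mat.T.groupby(samples["time_point"]).mean().T
    return ActivityMatrix(sample_matrix=mat, timepoint_matrix=tpm,
                          samples=samples)


class TestCluster:
    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(0.0, 0.3, size=(100, 6))
        hi = rng.normal(1.5, 0.3, size=(100, 6))
        mat = pd.DataFrame(
            np.vstack([lo, hi]),
            index=[f"e{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(6)],
        )
        res = mx.cluster_activity(_am_from_matrix(mat))
        truth = [0] * 100 + [1] * 100
        assert adjusted_rand_score(truth, res.labels.to_numpy()) >= 0.9

    def test_duplicating_rows_preserves_partition(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(
            np.vstack([rng.normal(0, 0.2, (20, 4)), rng.normal(2, 0.2, (20, 4))]),
            index=[f"e{i}" for i in range(40)],
        )
        res1 = mx.cluster_activity(_am_from_matrix(mat))
        dup = pd.concat([mat, mat.set_axis([f"d{i}" for i in range(40)])])
        res2 = mx.cluster_activity(_am_from_matrix(dup))
        orig = res2.labels.loc[mat.index]
        copy = res2.labels.loc[[f"d{i}" for i in range(40)]]
        assert adjusted_rand_score(res1.labels, orig) == 1.0
        assert (orig.to_numpy() == copy.to_numpy()).all()

    def test_row_order_invariant_merge_heights(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(0, 1, (30, 5)),
                           index=[f"e{i}" for i in range(30)])
        res1 = mx.cluster_activity(_am_from_matrix(mat))
        perm = mat.sample(frac=1, random_state=3)
        res2 = mx.cluster_activity(_am_from_matrix(perm))
        np.testing.assert_allclose(
            np.sort(res1.linkage[:, 2]), np.sort(res2.linkage[:, 2]), rtol=1e-9
        )

    def test_display_cap_leaves_distances_alone(self):
        mat = pd.DataFrame(
            [[0.0, 0.0], [3.0, 3.0], [3.1, 3.1], [0.1, 0.1]],
            index=list("abcd"),
        )
        res = mx.cluster_activity(_am_from_matrix(mat), cap_for_display=4.0)
        assert res.display_matrix.to_numpy().max() <= 4.0
        # linear activity 2^3.1 > 4: raw values exceed the display cap
        assert np.exp2(mat).to_numpy().max() > 4.0

    def test_constant_matrix_degenerates_with_warning(self):
        mat = pd.DataFrame(np.ones((5, 3)), index=list("abcde"))
        with pytest.warns(UserWarning):
            res = mx.cluster_activity(_am_from_matrix(mat))
        assert (res.labels == 1).all()

    def test_actives_concentrate_in_one_cluster(self, small_experiment):
        """Called-active elements should land overwhelmingly in one of the
        two top-level activity clusters."""
        res = mx.cluster_activity(small_experiment.activity)
        active = small_experiment.calls.active_elements()
        if len(active) >= 5:
            labs = res.labels.loc[active]
            assert labs.value_counts(normalize=True).iloc[0] >= 0.8


class TestPairLog2FC:
    @staticmethod
    def _toy_inputs():
        mat = pd.DataFrame(
            {"iPSC_r1": [1.0], "TD0_r1": [2.0]},
            index=pd.Index(["e1"], name="element_id"),
        )
        am = _am_from_matrix(mat, tps=["iPSC", "TD0"])
        expr = pd.DataFrame(
            {"iPSC_r1": [2.0], "TD0_r1": [8.0]},
            index=pd.Index(["g1"], name="gene_id"),
        )
        expr.attrs["samples"] = pd.DataFrame(
            {"time_point": ["iPSC", "TD0"]}, index=expr.columns
        )
        links = pd.DataFrame({"element_id": ["e1"], "gene_id": ["g1"]})
        return am, expr, links

    def test_closed_form_deltas(self):
        am, expr, links = self._toy_inputs()
        pairs = mx.pair_log2fc(am, expr, links, ("TD0", "iPSC"), pseudocount=0)
        assert pairs.d_activity.iloc[0] == pytest.approx(1.0)
        assert pairs.d_expression.iloc[0] == pytest.approx(2.0)

    def test_same_timepoint_contrast_all_zero(self):
        am, expr, links = self._toy_inputs()
        pairs = mx.pair_log2fc(am, expr, links, ("TD0", "TD0"))
        assert pairs.d_activity.iloc[0] == 0.0
        assert pairs.d_expression.iloc[0] == 0.0

    def test_missing_gene_dropped(self):
        am, expr, links = self._toy_inputs()
        links = pd.concat(
            [links, pd.DataFrame({"element_id": ["e1"], "gene_id": ["absent"]})]
        )
        pairs = mx.pair_log2fc(am, expr, links, ("TD0", "iPSC"))
        assert len(pairs) == 1

    def test_missing_expression_timepoint_refused(self):
        am, expr, links = self._toy_inputs()
        expr.attrs["samples"] = pd.DataFrame(
            {"time_point": ["TD0", "TD0"]}, index=expr.columns
        )
        with pytest.raises(ValueError, match="iPSC"):
            mx.pair_log2fc(am, expr, links, ("TD0", "iPSC"))

    def test_sign_agreement_for_true_actives(self, small_experiment):
        """With beta=1, Δ expression tracks the sign of Δ activity for most
        strongly moving truly active pairs."""
        exp = small_experiment
        truth = mx.SimTruth()
        expr = mx.simulate_expression(exp.design, truth, exp.truth_table, seed=21)
        links = pd.DataFrame(
            [
                {"element_id": e.element_id, "gene_id": g}
                for e in exp.design.elements
                for g in e.linked_genes
            ]
        )
        pairs = mx.pair_log2fc(exp.activity, expr, links, ("TD0", "iPSC"),
                               calls=exp.calls)
        ever_active = exp.truth_table.groupby("element_id")["is_active"].any()
        sub = pairs[
            pairs.element_id.map(ever_active).fillna(False)
            & (pairs.d_activity.abs() > 0.8)
        ]
        assert len(sub) >= 20
        agree = (np.sign(sub.d_activity) == np.sign(sub.d_expression)).mean()
        assert agree > 0.7


class TestConcordance:
    @staticmethod
    def _pairs(rows):
        return pd.DataFrame(
            rows, columns=["element_id", "gene_id", "contrast", "d_activity",
                           "d_expression", "active"]
        )

    def test_zero_cutoff_fraction_one(self):
        pairs = self._pairs(
            [("e1", "g1", "c", 0.5, -0.3, True), ("e2", "g2", "c", 0.1, 0.0, False)]
        )
        curve = mx.concordance_curve(pairs, cutoffs=[0.0])
        assert (curve.fraction == 1.0).all()

    def test_single_pair_threshold(self):
        pairs = self._pairs([("e1", "g1", "c", 1.0, 0.5, True)])
        curve = mx.concordance_curve(pairs, cutoffs=[0.4, 0.8])
        active = curve[curve.group == "active"].set_index("cutoff").fraction
        assert active.loc[0.4] == 1.0
        assert active.loc[0.8] == 0.0

    def test_curves_monotone_non_increasing(self):
        rng = np.random.default_rng(4)
        pairs = self._pairs(
            [
                (f"e{i}", f"g{i}", "c", rng.normal(0, 1), rng.normal(0, 1),
                 bool(rng.random() < 0.5))
                for i in range(300)
            ]
        )
        curve = mx.concordance_curve(pairs, cutoffs=np.linspace(0, 2, 21))
        for grp in ("active", "inactive"):
            f = curve[curve.group == grp].sort_values("cutoff").fraction.to_numpy()
            assert (np.diff(f) <= 1e-12).all()

    def test_empty_group_reported_missing(self):
        pairs = self._pairs([("e1", "g1", "c", 1.0, 1.0, True)])
        curve = mx.concordance_curve(pairs, cutoffs=[0.5])
        inactive = curve[(curve.group == "inactive")]
        assert math.isnan(inactive.fraction.iloc[0])

    def test_sign_concordance_helper(self):
        pairs = self._pairs(
            [("e1", "g1", "c", 1.0, 0.5, True), ("e2", "g2", "c", -1.0, 0.5, True)]
        )
        assert sign_concordance(pairs) == 0.5


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration with math.comb."""
    r1, r2, k = a + b, c + d, a + c
    N = r1 + r2

    def pmf(x):
        if x < max(0, k - r2) or x > min(k, r1):
            return 0.0
        return (
            math.comb(r1, x) * math.comb(r2, k - x) / math.comb(N, k)
        )

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(0, k + 1) if pmf(x) <= p_obs * (1 + 1e-7))


class TestOverlapEnrichment:
    @staticmethod
    def _setup(overlap_flags, active_flags):
        n = len(overlap_flags)
        ids = [f"e{i}" for i in range(n)]
        intervals = {
            ids[i]: mx.GenomicInterval("chr1", 1000 * i + 100, 1000 * i + 370)
            for i in range(n)
        }
        fs = mx.FeatureSet(
            "ext",
            [
                mx.GenomicInterval("chr1", 1000 * i + 200, 1000 * i + 250)
                for i in range(n)
                if overlap_flags[i]
            ],
        )
        sig = pd.DataFrame(
            {"iPSC": active_flags, "TD0": [False] * n, "TD30": [False] * n},
            index=pd.Index(ids, name="element_id"),
        )
        long = sig.stack().rename("significant").reset_index()
        long.columns = ["element_id", "time_point", "significant"]
        long["activity_log2"] = 0.0
        long["p_value"] = 0.5
        ct = mx.CallTable(long, alpha=0.05, n_tests=n, cutoff=1.0)
        return ct, [fs], intervals

    def test_matches_hypergeometric_enumeration(self):
        # table a=8, b=2, c=1, d=5
        overlap = [True] * 8 + [False] * 2 + [True] * 1 + [False] * 5
        active = [True] * 10 + [False] * 6
        ct, ext, ivs = self._setup(overlap, active)
        enrich, _ = mx.overlap_enrichment(ct, ext, ivs)
        row = enrich.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (8, 2, 1, 5)
        assert row.odds_ratio == pytest.approx((8 * 5) / (2 * 1))
        assert row.p_value == pytest.approx(_fisher_oracle(8, 2, 1, 5), rel=1e-9)

    @pytest.mark.parametrize("table", [(3, 1, 2, 4), (0, 5, 5, 0), (2, 2, 2, 2)])
    def test_more_small_tables_match_oracle(self, table):
        a, b, c, d = table
        got, _ = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided"), None
        assert got[1] == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-9)

    def test_full_coverage_set_degenerates(self):
        overlap = [True] * 10
        active = [True] * 4 + [False] * 6
        ct, ext, ivs = self._setup(overlap, active)
        enrich, _ = mx.overlap_enrichment(ct, ext, ivs)
        assert enrich.iloc[0].p_value == pytest.approx(1.0)
        assert np.isnan(enrich.iloc[0].odds_ratio) or np.isinf(
            enrich.iloc[0].odds_ratio
        )

    def test_margins_conserved_and_upset_totals(self):
        rng = np.random.default_rng(6)
        overlap = list(rng.random(40) < 0.4)
        active = list(rng.random(40) < 0.3)
        ct, ext, ivs = self._setup(overlap, active)
        enrich, upset = mx.overlap_enrichment(ct, ext, ivs)
        row = enrich.iloc[0]
        assert row.a + row.b == sum(active)
        assert row.c + row.d == 40 - sum(active)
        assert (upset.n_active.sum() + upset.n_inactive.sum()) == 40

    def test_type_one_error_calibrated_under_permutation(self):
        """Permuting active labels breaks any association: Fisher p < 0.05
        should occur in ≲5% of permutations."""
        rng = np.random.default_rng(8)
        overlap = np.array([True] * 30 + [False] * 70)
        n_active = 25
        n_sig = 0
        n_perm = 1000
        for _ in range(n_perm):
            active = np.zeros(100, bool)
            active[rng.choice(100, n_active, replace=False)] = True
            a = int((active & overlap).sum())
            b = n_active - a
            c = int(overlap.sum()) - a
            d = 100 - a - b - c
            _, p = stats.fisher_exact([[a, b], [c, d]])
            n_sig += p < 0.05
        assert n_sig / n_perm <= 0.07


class TestKSCompare:
    def test_identical_groups_stat_zero(self):
        g = {"a": np.arange(50.0), "b": np.arange(50.0)}
        out = mx.ks_compare(g)
        assert out.ks_stat.iloc[0] == 0.0
        assert out.p_value.iloc[0] == pytest.approx(1.0)

    def test_shifted_ranges_definitional_oracle(self):
        a = np.arange(1, 101, dtype=float)
        b = np.arange(51, 151, dtype=float)
        out = mx.ks_compare({"a": a, "b": b})
        # brute-force max CDF gap over the pooled support
        gap = max(
            abs((a <= x).mean() - (b <= x).mean())
            for x in np.concatenate([a, b])
        )
        assert gap == pytest.approx(0.5)
        assert out.ks_stat.iloc[0] == pytest.approx(gap, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_definitional_statistic(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 37), rng.normal(0.4, 1.3, 59)
        out = mx.ks_compare({"a": a, "b": b})
        gap = max(
            abs((a <= x).mean() - (b <= x).mean())
            for x in np.concatenate([a, b])
        )
        assert out.ks_stat.iloc[0] == pytest.approx(gap, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 5"):
            mx.ks_compare({"a": np.arange(3.0), "b": np.arange(10.0)})

    def test_three_groups_all_pairs(self):
        g = {k: np.arange(10.0) + i for i, k in enumerate("abc")}
        out = mx.ks_compare(g)
        assert len(out) == 3

    def test_identical_generating_law_rarely_significant(self):
        """TFBS-count-style null: both groups drawn identically → the KS test
        rejects at ~nominal rate (scaled-down calibration)."""
        rng = np.random.default_rng(12)
        n_sig = 0
        reps = 200
        for _ in range(reps):
            a = rng.poisson(30, 80)
            b = rng.poisson(30, 120)
            out = mx.ks_compare({"active": a, "inactive": b})
            n_sig += out.p_value.iloc[0] < 0.05
        assert n_sig / reps <= 0.07

    def test_ecdf_summary_hits_one(self):
        out = ecdf_summary({"a": np.arange(5.0)})
        assert out["a"].iloc[-1] == 1.0


class TestCountTFBS:
    def test_empty_table_all_zero(self):
        hits = pd.DataFrame(columns=["sequence_name", "q-value"])
        counts = mx.count_tfbs(hits, ["e1", "e2"])
        assert (counts == 0).all()

    def test_threshold_filter(self):
        hits = pd.DataFrame(
            {"sequence_name": ["e1"] * 3, "q-value": [0.01, 0.04, 0.2]}
        )
        counts = mx.count_tfbs(hits, ["e1"], fdr_max=0.05)
        assert counts.loc["e1"] == 2

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(9)
        ids = [f"e{i}" for i in range(10)]
        rows = [
            {"sequence_name": ids[rng.integers(10)], "q-value": float(rng.random())}
            for _ in range(100)
        ]
        hits = pd.DataFrame(rows)
        counts = mx.count_tfbs(hits, ids, fdr_max=0.05)
        for eid in ids:
            manual = sum(
                1 for r in rows
                if r["sequence_name"] == eid and r["q-value"] <= 0.05
            )
            assert counts.loc[eid] == manual

    def test_unknown_sequences_bucketed(self):
        hits = pd.DataFrame(
            {"sequence_name": ["e1", "mystery"], "q-value": [0.01, 0.01]}
        )
        counts = mx.count_tfbs(hits, ["e1"])
        assert counts.loc["e1"] == 1
        assert counts.attrs.get("unassigned") == 1
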