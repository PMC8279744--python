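"""Per-bin tests, cluster formation, permutation nulls, significance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gazecourse.clusters import (
    BinTestResult,
    Cluster,
    PermutationNull,
    cluster_analysis,
    cluster_pvalue,
    find_clusters,
    per_bin_test,
    permutation_null,
    zero_reference,
)


def make_table(rng, n_p=8, n_items=6, n_bins=5, effect=0.0, noise=0.5, occ_half=True):
    """Long log-ratio table; `effect` is added to the female-occupation rows."""
    rows = []
    for p in range(1, n_p + 1):
        for i in range(1, n_items + 1):
            occ = "female" if (i <= n_items // 2) == occ_half else "male"
            for b in range(n_bins):
                val = rng.normal(0.0, noise) + (effect if occ == "female" else 0.0)
                rows.append(
                    {
                        "participant": p,
                        "trial_id": i,
                        "occupation_stereotype": occ,
                        "action_stereotype": "female",
                        "bin": b,
                        "log_ratio": val,
                    }
                )
    return pd.DataFrame(rows)


class TestPerBinTest:
    def test_all_zero_response_gives_t_zero(self, rng):
        table = make_table(rng, effect=0.0)
        table["log_ratio"] = 0.0
        res = per_bin_test(table, 0)
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_paired_t_oracle(self, rng):
        """With the paired statistic, the per-bin t must equal the classical
        paired t on participant-by-condition means."""
        table = make_table(rng, effect=0.4)
        res = per_bin_test(table, 2)
        agg = (
            table[table.bin == 2]
            .groupby(["participant", "occupation_stereotype"])["log_ratio"]
            .mean()
            .unstack()
        )
        t, p = stats.ttest_rel(agg["female"], agg["male"])
        assert np.isclose(res.t, t) and np.isclose(res.p, p)

    def test_mixed_model_agrees_with_paired_on_balanced_data(self, rng):
        """On balanced data with participant-level random variation the
        crossed-intercepts mixed model and the participant-aggregated paired
        t estimate the same contrast; t values should land close."""
        table = make_table(rng, n_p=10, n_items=6, n_bins=1, effect=0.5, noise=0.3)
        # add participant offsets (absorbed by both approaches)
        offs = dict(zip(range(1, 11), rng.normal(0, 0.4, 10)))
        table["log_ratio"] += table["participant"].map(offs)
        mixed = per_bin_test(table, 0, stat="mixed")
        paired = per_bin_test(table, 0, stat="paired")
        assert mixed.converged
        assert np.sign(mixed.t) == np.sign(paired.t)
        assert abs(mixed.t - paired.t) < 0.35 * abs(paired.t) + 0.5

    def test_single_level_contrast_raises(self, rng):
        table = make_table(rng)
        with pytest.raises(ValueError, match="two levels"):
            per_bin_test(table[table.occupation_stereotype == "female"], 0)

    def test_empty_scope_raises(self, rng):
        with pytest.raises(ValueError, match="no data"):
            per_bin_test(make_table(rng), 99)


class TestZeroReference:
    def test_doubles_rows_with_zero_label(self, rng):
        table = make_table(rng)
        aug = zero_reference(table)
        assert len(aug) == 2 * len(table)
        assert (aug[aug.ref_label == "zero"]["log_ratio"] == 0.0).all()

    def test_all_zero_data_indistinguishable(self, rng):
        table = make_table(rng)
        table["log_ratio"] = 0.0
        res = per_bin_test(zero_reference(table), 0, contrast="zero")
        assert res.t == 0.0

    def test_shift_increases_t_monotonically(self, rng):
        base = make_table(rng, n_bins=1)
        ts = []
        for c in (0.0, 0.3, 0.6, 0.9):
            shifted = base.copy()
            shifted["log_ratio"] = base["log_ratio"] + c
            ts.append(per_bin_test(zero_reference(shifted), 0, contrast="zero").t)
        assert all(b > a for a, b in zip(ts, ts[1:]))


class TestFindClusters:
    @staticmethod
    def res(bin_idx, t, p):
        return BinTestResult(bin_idx, t, p, "condition", ())

    def test_no_significant_bins(self):
        out = find_clusters([self.res(b, 0.5, 0.6) for b in range(10)])
        assert out == []

    def test_single_cluster_summed_t(self):
        results = [self.res(b, 2.0 if 5 <= b <= 9 else 0.1, 0.01 if 5 <= b <= 9 else 0.9)
                   for b in range(12)]
        out = find_clusters(results)
        assert len(out) == 1
        cl = out[0]
        assert (cl.start_bin, cl.end_bin, cl.summed_t) == (5, 9, 10.0)

    def test_gap_splits_clusters(self):
        results = [self.res(2, 2.2, 0.03), self.res(3, 0.1, 0.9), self.res(4, 2.5, 0.02)]
        out = find_clusters(results)
        assert [(c.start_bin, c.end_bin) for c in out] == [(2, 2), (4, 4)]

    def test_sign_change_splits_clusters(self):
        results = [self.res(0, 2.2, 0.03), self.res(1, -2.4, 0.02), self.res(2, -2.1, 0.04)]
        out = find_clusters(results)
        assert [(c.start_bin, c.end_bin) for c in out] == [(0, 0), (1, 2)]
        assert out[1].summed_t == pytest.approx(-4.5)

    def test_min_length_filter(self):
        results = [self.res(0, 2.2, 0.03), self.res(5, 2.0, 0.04), self.res(6, 2.0, 0.04)]
        out = find_clusters(results, min_length=2)
        assert [(c.start_bin, c.end_bin) for c in out] == [(5, 6)]


class TestPermutationNull:
    def test_deterministic_under_seed(self, rng):
        table = make_table(rng)
        a = permutation_null(table, "condition-swap", n_iterations=50, seed=9)
        b = permutation_null(table, "condition-swap", n_iterations=50, seed=9)
        assert np.array_equal(a.max_abs_summed_t, b.max_abs_summed_t)

    def test_constant_zero_data_gives_all_zero_null(self, rng):
        table = make_table(rng)
        table["log_ratio"] = 0.0
        null = permutation_null(table, "condition-swap", n_iterations=30, seed=1)
        assert (null.max_abs_summed_t == 0.0).all()

    def test_invalid_arguments(self, rng):
        table = make_table(rng)
        with pytest.raises(ValueError, match="n_iterations"):
            permutation_null(table, "condition-swap", n_iterations=0, seed=1)
        with pytest.raises(ValueError, match="unknown scheme"):
            permutation_null(table, "bogus", n_iterations=10, seed=1)

    def test_null_quantile_of_observed_is_calibrated(self):
        """Under exchangeable (null) data the observed max cluster mass falls
        at a uniform quantile of its permutation null: the rate of landing in
        the top 10% should be ~10%."""
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            table = make_table(rng, n_p=6, n_items=4, n_bins=8)
            null = permutation_null(table, "condition-swap", n_iterations=60, seed=rep)
            from gazecourse.clusters import _contrast_t, _max_cluster_mass, _stack

            stacked = _stack(table, "occupation_stereotype", "female")
            t, df = _contrast_t(stacked.values, stacked.labels)
            obs = _max_cluster_mass(t, stats.t.ppf(0.975, df))
            rank = (null.max_abs_summed_t >= obs).mean()
            hits += rank <= 0.10
        # binomial(60, 0.1): 3 SE band around 6
        assert abs(hits - 6) <= 3 * np.sqrt(60 * 0.1 * 0.9) + 1e-9

    def test_observed_mass_monotone_in_effect_scale(self):
        from gazecourse.clusters import _contrast_t, _max_cluster_mass, _stack

        rng = np.random.default_rng(3)
        table = make_table(rng, effect=0.3)
        masses = []
        for c in (1.0, 2.0, 4.0):
            scaled = table.copy()
            fem = scaled.occupation_stereotype == "female"
            scaled.loc[fem, "log_ratio"] *= c
            stacked = _stack(scaled, "occupation_stereotype", "female")
            t, df = _contrast_t(stacked.values, stacked.labels)
            masses.append(_max_cluster_mass(t, stats.t.ppf(0.975, df)))
        assert masses[0] <= masses[1] <= masses[2]


class TestClusterPvalue:
    def cluster(self, summed):
        return Cluster("condition", (), 0, 4, tuple([summed / 5] * 5))

    def test_extreme_cluster_significant(self):
        null = PermutationNull("condition-swap", (), 2000, np.zeros(2000), 0)
        sig = cluster_pvalue(self.cluster(10.0), null)
        assert np.isclose(sig.p, 1 / 2001) and sig.significant

    def test_median_cluster_not_significant(self, rng):
        null = PermutationNull("condition-swap", (), 999, rng.normal(10, 2, 999) ** 0 * np.abs(rng.normal(10, 2, 999)), 0)
        sig = cluster_pvalue(self.cluster(float(np.median(null.max_abs_summed_t))), null)
        assert 0.4 < sig.p < 0.6 and not sig.significant

    def test_boundary_p_is_strict(self):
        # 39 of 1599 null values >= observed: p = 40/1600 = 0.025 exactly
        null_vals = np.concatenate([np.full(39, 5.0), np.full(1560, 0.0)])
        null = PermutationNull("condition-swap", (), 1599, null_vals, 0)
        sig = cluster_pvalue(self.cluster(4.0), null)
        assert np.isclose(sig.p, 0.025) and not sig.significant


class TestClusterAnalysis:
    def test_detects_injected_condition_effect(self, rng):
        table = make_table(rng, n_p=10, n_items=8, n_bins=10, effect=0.0)
        window = table.bin.isin([4, 5, 6]) & (table.occupation_stereotype == "female")
        table.loc[window, "log_ratio"] += 1.0
        res = cluster_analysis(table, schemes=("condition-swap",), n_iterations=100, seed=0)
        cl = res["clusters"]
        assert cl.significant.any()
        top = cl.loc[cl.summed_t.abs().idxmax()]
        assert top.start_bin >= 3 and top.end_bin <= 7

    def test_full_output_reproducible(self, small_logratio):
        a = cluster_analysis(small_logratio, n_iterations=40, seed=5)
        b = cluster_analysis(small_logratio, n_iterations=40, seed=5)
        pd.testing.assert_frame_equal(a["clusters"], b["clusters"])

    def test_observed_stage_matches_per_bin_test(self, rng):
        """The vectorized observed stage must equal the public per-bin test."""
        table = make_table(rng, n_bins=4, effect=0.3)
        res = cluster_analysis(table, schemes=("condition-swap",), n_iterations=1, seed=0)
        tests = res["bin_tests"][("condition-swap", "action_stereotype", "female")]
        for bt in tests:
            ref = per_bin_test(table, bt.bin)
            assert np.isclose(bt.t, ref.t)
            assert np.isclose(bt.p, ref.p)

    def test_zero_scheme_matches_one_sample_oracle(self, rng):
        table = make_table(rng, n_bins=3)
        cell = table[table.occupation_stereotype == "female"]
        res = cluster_analysis(table, schemes=("female-vs-zero",), n_iterations=1, seed=0)
        tests = res["bin_tests"][
            ("female-vs-zero", "action_stereotype", "female", "occupation", "female")
        ]
        for bt in tests:
            pmeans = cell[cell.bin == bt.bin].groupby("participant")["log_ratio"].mean()
            t, p = stats.ttest_1samp(pmeans, 0.0)
            assert np.isclose(bt.t, t) and np.isclose(bt.p, p)
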