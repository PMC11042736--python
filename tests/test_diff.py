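import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cleavemap.diff import (
    ModelConfig,
    bh_adjust,
    call_sites,
    call_tss,
    crosscheck_tss_vs_cleavage,
    estimate_dispersion,
    filter_positions,
    nb_lrt,
    tmm_factors,
)
from cleavemap.end_counting import EndCountTable, make_library_meta
from _oracles import grid_search_lrt, naive_tmm, textbook_bh


def make_table(counts, conditions, sizes=None, rpph=True):
    libs = [f"lib{i}" for i in range(counts.shape[1])]
    frame = pd.DataFrame(
        counts,
        index=pd.MultiIndex.from_tuples(
            [("chr", "+", i) for i in range(counts.shape[0])],
            names=["reference", "strand", "position"],
        ),
        columns=libs,
    )
    if sizes is None:
        sizes = frame.sum(axis=0).astype(float)
    else:
        sizes = pd.Series(dict(zip(libs, sizes)))
    meta = make_library_meta(libs, conditions, rpph_treated=rpph)
    return EndCountTable(frame, sizes, meta)


class TestFilterPositions:
    conds = ["targeting"] * 3 + ["nontargeting"] * 3

    def test_cpm_threshold_on_targeting_replicates(self):
        # library size 1e6 so counts are CPM directly
        counts = np.array([
            [12, 11, 10, 0, 0, 0],   # retained: >=10 CPM in all 3 targeting
            [12, 11, 9, 0, 0, 0],    # dropped: only 2 replicates pass
            [0, 0, 0, 900, 900, 900] # dropped: nontargeting does not count
        ])
        t = make_table(counts, self.conds, sizes=[1e6] * 6)
        kept = filter_positions(t, ModelConfig())
        assert list(kept.counts.index.get_level_values("position")) == [0]

    def test_requires_enough_targeting_libraries(self):
        t = make_table(np.ones((2, 4), dtype=int),
                       ["targeting"] * 2 + ["nontargeting"] * 2)
        with pytest.raises(ValueError, match="targeting"):
            filter_positions(t, ModelConfig())

    def test_library_sizes_survive_filtering(self):
        counts = np.array([[50, 50, 50, 5, 5, 5], [1, 1, 1, 1, 1, 1]])
        t = make_table(counts, self.conds, sizes=[1e3] * 6)
        kept = filter_positions(t, ModelConfig())
        pd.testing.assert_series_equal(kept.library_sizes, t.library_sizes)


class TestTmmFactors:
    def test_identical_libraries_give_exactly_one(self):
        y = np.tile(np.arange(1, 51)[:, None], (1, 4)).astype(float)
        np.testing.assert_array_equal(tmm_factors(y, y.sum(0)), np.ones(4))

    def test_global_scaling_gives_exactly_one(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 200, size=100).astype(float)
        y = np.column_stack([a, 2 * a])
        np.testing.assert_array_equal(tmm_factors(y, y.sum(0)), np.ones(2))

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            y = rng.negative_binomial(4, 0.02, size=(200, 4)).astype(float)
            y[:, 2] *= rng.uniform(0.5, 2.0)
            N = y.sum(0)
            np.testing.assert_allclose(
                tmm_factors(y, N), naive_tmm(y, N), atol=1e-8
            )

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(30, size=(150, 5)).astype(float)
        f = tmm_factors(y, y.sum(0))
        assert abs(np.log(f).mean()) < 1e-12

    def test_zero_overlap_library_warns_factor_one(self):
        y = np.zeros((20, 3))
        y[:10, 0] = 50
        y[:10, 1] = 55
        y[10:, 2] = 60  # no shared expressed position with reference
        with pytest.warns(UserWarning, match="no expressed positions"):
            f = tmm_factors(y, np.array([500.0, 550.0, 600.0]))
        assert np.isfinite(f).all()


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_and_single(self):
        np.testing.assert_allclose(bh_adjust([0.05] * 5), 0.05)
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_matches_textbook_procedure_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), textbook_bh(p), atol=1e-12)

    def test_nan_passthrough_and_range_check(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[[0, 2]]).any()
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_fdr_dominates_p_and_stays_in_unit_interval(self, p):
        out = bh_adjust(p)
        assert (out >= np.asarray(p) - 1e-12).all()
        assert ((out >= 0) & (out <= 1)).all()


class TestEstimateDispersion:
    groups = np.array(["a"] * 3 + ["b"] * 3)
    offsets = np.zeros(6)

    def test_poisson_data_hits_near_zero(self):
        rng = np.random.default_rng(11)
        mu = rng.lognormal(3.5, 1.0, size=2000)
        y = rng.poisson(mu[:, None], size=(2000, 6)).astype(float)
        assert estimate_dispersion(y, self.groups, self.offsets) <= 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(12)
        phi, r = 0.2, 5.0
        mu = rng.lognormal(3.5, 1.0, size=2000)
        y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 6))
        est = estimate_dispersion(y.astype(float), self.groups, self.offsets)
        assert 0.15 <= est <= 0.25

    def test_constant_counts_hit_lower_bound(self):
        y = np.full((50, 6), 20.0)
        est = estimate_dispersion(y, self.groups, self.offsets)
        assert est <= 2e-6

    def test_no_replication_rejected(self):
        with pytest.raises(ValueError, match="replication"):
            estimate_dispersion(np.ones((5, 2)), np.array(["a", "b"]), np.zeros(2))

    def test_moment_mode_returns_per_position(self):
        rng = np.random.default_rng(13)
        y = rng.poisson(50, size=(30, 6)).astype(float)
        est = estimate_dispersion(y, self.groups, self.offsets,
                                  mode="per-position-moment")
        assert est.shape == (30,)
        assert (est >= 1e-6).all()


class TestNbLrt:
    groups = np.array(["pos"] * 3 + ["neg"] * 3)

    def test_equal_means_give_null_statistic(self):
        y = np.array([[20.0, 20, 20, 20, 20, 20]])
        res = nb_lrt(y, self.groups, np.zeros(6), 0.1, positive_level="pos")
        assert res.lrt_stat.iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert res.log2fc.iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert res.pvalue.iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_poisson_limit_equals_closed_form_deviance(self):
        """At dispersion 0 the statistic is the Poisson deviance
        2*sum y log(y/mu_hat) between the two nested fits."""
        y = np.array([[5.0, 9, 7, 40, 52, 46]])
        res = nb_lrt(y, self.groups, np.zeros(6), 0.0, positive_level="pos")
        mu_full = np.r_[np.repeat(y[0, :3].mean(), 3), np.repeat(y[0, 3:].mean(), 3)]
        mu_null = np.repeat(y.mean(), 6)
        dev = 2 * (np.sum(y[0] * np.log(y[0] / mu_null))
                   - np.sum(y[0] * np.log(y[0] / mu_full)))
        assert res.lrt_stat.iloc[0] == pytest.approx(dev, abs=1e-8)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            y = rng.integers(0, 51, size=6).astype(float)
            res = nb_lrt(y[None, :], self.groups, np.zeros(6), 0.2,
                         positive_level="pos")
            oracle = grid_search_lrt(y, 0.2)
            assert res.lrt_stat.iloc[0] == pytest.approx(oracle, abs=1e-3)

    def test_zero_group_reports_capped_log2fc(self):
        y = np.array([[30.0, 35, 28, 0, 0, 0], [0.0, 0, 0, 30, 35, 28]])
        res = nb_lrt(y, self.groups, np.zeros(6), 0.1, positive_level="pos")
        assert res.log2fc.iloc[0] == 20.0
        assert res.log2fc.iloc[1] == -20.0

    def test_offset_translation_leaves_test_invariant(self):
        """A constant added to every offset shifts both intercepts equally:
        the statistic and the fold change are unchanged."""
        rng = np.random.default_rng(8)
        y = rng.poisson(40, size=(20, 6)).astype(float)
        res1 = nb_lrt(y, self.groups, np.zeros(6), 0.1, positive_level="pos")
        res2 = nb_lrt(y, self.groups, np.full(6, 3.7), 0.1, positive_level="pos")
        np.testing.assert_allclose(res1.log2fc, res2.log2fc, atol=1e-6)
        np.testing.assert_allclose(res1.lrt_stat, res2.lrt_stat, atol=1e-6)


def make_diff(fdr, log2fc):
    n = len(fdr)
    idx = pd.MultiIndex.from_tuples(
        [("chr", "+", i) for i in range(n)],
        names=["reference", "strand", "position"],
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "lrt_stat": 1.0, "pvalue": np.asarray(fdr) / 2,
         "fdr": fdr, "converged": True},
        index=idx,
    )


class TestCallSites:
    def test_top_n_then_lfc_filter(self):
        fdr = np.linspace(1e-10, 0.9, 150)
        lfc = np.full(150, 6.0)
        sites = call_sites(make_diff(fdr, lfc), ModelConfig())
        assert len(sites) == 100
        assert (sites.fdr.values == np.sort(sites.fdr.values)).all()

    def test_no_sites_above_threshold(self):
        sites = call_sites(
            make_diff(np.linspace(0, 1, 50), np.full(50, 4.0)), ModelConfig()
        )
        assert sites.empty  # log2fc must strictly exceed the threshold

    def test_subset_of_top_passes(self):
        fdr = np.linspace(1e-10, 0.9, 150)
        lfc = np.where(np.arange(150) % 2 == 0, 6.0, 1.0)
        sites = call_sites(make_diff(fdr, lfc), ModelConfig())
        # among the top 100 by fdr, exactly the even-indexed 50 pass
        assert len(sites) == 50
        assert (sites.log2fc == 6.0).all()
        assert (np.diff(sites.fdr.values) >= 0).all()

    def test_tie_break_prefers_large_effect_then_coordinates(self):
        diff = make_diff([0.01, 0.01, 0.01], [5.0, 8.0, 5.0])
        sites = call_sites(diff, ModelConfig(top_n=2))
        positions = list(sites.index.get_level_values("position"))
        assert positions == [1, 0]


class TestTssMachinery:
    def test_missing_untreated_libraries_rejected(self):
        counts = np.tile([50, 50, 50, 50, 50, 50], (5, 1))
        t = make_table(counts, ["targeting"] * 3 + ["nontargeting"] * 3, rpph=True)
        with pytest.raises(ValueError, match="untreated"):
            call_tss(t, ModelConfig())

    def test_crosscheck_disjoint_and_identical(self):
        a = make_diff([0.01] * 10, [6.0] * 10)
        b = a.copy()
        n, shared = crosscheck_tss_vs_cleavage(a, b, k=10)
        assert n == 10
        c = make_diff([0.01] * 10, [6.0] * 10)
        c.index = pd.MultiIndex.from_tuples(
            [("chr", "-", i + 500) for i in range(10)],
            names=["reference", "strand", "position"],
        )
        n2, shared2 = crosscheck_tss_vs_cleavage(a, c, k=10)
        assert n2 == 0 and shared2 == []

    def test_crosscheck_k_larger_than_set_warns(self):
        a = make_diff([0.01] * 5, [6.0] * 5)
        with pytest.warns(UserWarning, match="using all"):
            n, _ = crosscheck_tss_vs_cleavage(a, a, k=50)
        assert n == 5
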