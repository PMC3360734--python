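"""Ensemble statistics: condition table, aggregation, tests, mean-SD
scaling, the gamma cell-event generator and optimal region allocation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import angioquant.ensemble as ens


class TestConditionTable:
    def test_vegf_gradient_row(self):
        spec = ens.condition_from_table1("VEGF Grad.")
        assert spec.nominal_average["VEGF"] == pytest.approx(30.0)
        assert spec.nominal_gradient["VEGF"] == pytest.approx(20.0)

    def test_vegf_plus_s1p_row(self):
        spec = ens.condition_from_table1("VEGF + S1P")
        assert spec.nominal_average["S1P"] == pytest.approx(125.0)
        assert spec.nominal_gradient["S1P"] == pytest.approx(250.0)
        assert spec.nominal_gradient["VEGF"] == pytest.approx(0.0)

    def test_control_has_no_gradient(self):
        spec = ens.condition_from_table1("Control")
        assert all(v == 0 for v in spec.nominal_gradient.values())

    def test_average_is_arithmetic_mean_of_channels(self):
        for label in ens.CONDITION_LABELS:
            spec = ens.condition_from_table1(label)
            for s, v in spec.nominal_average.items():
                lo = spec.monolayer_channel.get(s, 0.0)
                hi = spec.opposite_channel.get(s, 0.0)
                assert v == pytest.approx((lo + hi) / 2)

    def test_unknown_label_lists_valid_ones(self):
        with pytest.raises(ValueError, match="Control"):
            ens.condition_from_table1("VEGF Bolus")


def table_from(groups):
    rows = []
    for dev, values in groups.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "condition": "c",
                    "device_id": dev,
                    "region_index": i,
                    "M_cyto": float(v),
                }
            )
    return pd.DataFrame(rows)


class TestAggregate:
    def test_device_mean_and_sd(self):
        stats_list, cond = ens.aggregate(table_from({"D0": [2, 4, 6]}), "M_cyto")
        assert stats_list[0].mean == pytest.approx(4.0)
        assert stats_list[0].sd == pytest.approx(2.0)

    def test_condition_mean_and_se_from_device_means(self):
        stats_list, cond = ens.aggregate(
            table_from({"D0": [3, 3], "D1": [5, 5]}), "M_cyto"
        )
        assert cond.loc[0, "mean"] == pytest.approx(4.0)
        assert cond.loc[0, "se"] == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ens.aggregate(pd.DataFrame(columns=["condition", "device_id", "M_cyto"]), "M_cyto")

    def test_missing_metric_rejected(self):
        with pytest.raises(KeyError):
            ens.aggregate(table_from({"D0": [1, 2]}), "J_cyto")

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(perm_seed=st.integers(0, 10**6))
    def test_permutation_invariance(self, perm_seed):
        df = table_from({"D0": [1.0, 2.0, 5.0], "D1": [2.0, 2.5], "D2": [9.0, 1.0]})
        shuffled = df.sample(frac=1, random_state=perm_seed).reset_index(drop=True)
        a, ca = ens.aggregate(df, "M_cyto")
        b, cb = ens.aggregate(shuffled, "M_cyto")
        assert [(d.device_id, d.mean, d.sd) for d in a] == [
            (d.device_id, d.mean, d.sd) for d in b
        ]
        pd.testing.assert_frame_equal(ca, cb)


class TestSignificance:
    @pytest.mark.parametrize(
        "p, marker", [(0.07, "*"), (0.03, "**"), (0.001, "***"), (0.5, "")]
    )
    def test_marker_thresholds(self, p, marker):
        assert ens.significance_marker(p) == marker

    def test_identical_groups_not_significant(self):
        p, marker = ens.test_vs_control([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0 and marker == ""

    def test_clear_shift_detected(self):
        # 2-sigma shift at n = 30 per group: overwhelmingly significant
        rng = np.random.default_rng(0)
        a = rng.normal(2.0, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        p, marker = ens.test_vs_control(a, b)
        assert p < 0.005 and marker == "***"

    def test_welch_vs_pooled_agree_for_equal_variances(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 1.0, 40)
        b = rng.normal(0.5, 1.0, 40)
        pw, _ = ens.test_vs_control(a, b, welch=True)
        pp_, _ = ens.test_vs_control(a, b, welch=False)
        assert pw == pytest.approx(pp_, rel=0.05)


class TestMeanSdScaling:
    def test_exact_proportionality_recovered(self):
        ds = [
            ens.DeviceStats(f"D{i}", "c", mean=m, sd=0.4 * m, n_regions=10)
            for i, m in enumerate([1.0, 2.0, 5.0, 8.0])
        ]
        slope, intercept, r2 = ens.mean_sd_regression(ds)
        assert slope == pytest.approx(0.4)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_sd_gives_zero_slope_and_r2(self):
        ds = [
            ens.DeviceStats(f"D{i}", "c", mean=m, sd=1.5, n_regions=10)
            for i, m in enumerate([1.0, 2.0, 5.0])
        ]
        slope, _, r2 = ens.mean_sd_regression(ds)
        assert slope == 0.0 and r2 == 0.0

    def test_too_few_devices_rejected(self):
        ds = [ens.DeviceStats("D0", "c", 1.0, 0.5, 5)]
        with pytest.raises(ValueError):
            ens.mean_sd_regression(ds)

    def test_constant_cv_ensemble_slope_near_cv(self):
        df = ens.simulate_ensemble(14, 37, (1.0, 10.0), cv=0.4, seed=42)
        stats_list, _ = ens.aggregate(df, "M_cyto")
        slope, _, _ = ens.mean_sd_regression(stats_list)
        assert 0.3 <= slope <= 0.5

    def test_slope_converges_to_cv_with_many_regions(self):
        df = ens.simulate_ensemble(10, 500, (1.0, 10.0), cv=0.4, seed=3)
        stats_list, _ = ens.aggregate(df, "M_cyto")
        slope, _, _ = ens.mean_sd_regression(stats_list)
        assert slope == pytest.approx(0.4, abs=0.05)


class TestGenerativeModel:
    def test_same_seed_reproduces_table(self):
        a = ens.simulate_ensemble(4, 10, (1.0, 5.0), 0.4, seed=9)
        b = ens.simulate_ensemble(4, 10, (1.0, 5.0), 0.4, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_sample_mean_within_sampling_error(self):
        mu = 5.0
        df = ens.simulate_ensemble(1, 10**4, (mu, mu), 0.5, seed=11)
        v = df["M_cyto"].to_numpy()
        se = mu * 0.5 / math.sqrt(len(v))
        assert abs(v.mean() - mu) < 3 * se

    def test_region_totals_follow_gamma_law(self):
        # sums of exponential cell events are gamma distributed
        cv = 0.5
        mu = 5.0
        df = ens.simulate_ensemble(1, 10**4, (mu, mu), cv, seed=7)
        v = df["M_cyto"].to_numpy()
        shape = 1 / cv**2
        res = stats.kstest(v, lambda x: stats.gamma.cdf(x, shape, scale=mu * cv**2))
        assert res.pvalue > 0.01

    def test_constant_fano_regime_variance_proportional_to_mean(self):
        theta = 0.25
        df = ens.simulate_ensemble(
            20, 400, (2.0, 20.0), cv=0.4, regime="constant-fano",
            cell_event_scale=theta, seed=13,
        )
        grp = df.groupby("device_id")["M_cyto"]
        fano = (grp.var() / grp.mean()).to_numpy()
        assert np.all(np.abs(fano - theta) < 0.1 * max(1.0, 1.0 / theta) * theta + 0.05)

    def test_variance_decomposition_on_balanced_table(self):
        df = ens.simulate_ensemble(12, 30, (1.0, 10.0), 0.4, seed=21)
        v = df["M_cyto"].to_numpy().reshape(12, 30)
        total = v.var()
        within = v.var(axis=1).mean()
        between = v.mean(axis=1).var()
        assert total == pytest.approx(within + between, rel=1e-9)


class TestVarianceRatio:
    def test_zero_within_device_variance(self):
        df = table_from({"D0": [2, 2, 2], "D1": [5, 5, 5]})
        assert ens.variance_ratio(df, "M_cyto") == 0.0

    def test_known_variance_components(self):
        rng = np.random.default_rng(11)
        groups = {}
        for d in range(50):
            mu = rng.normal(50.0, 1.0)  # between-device sd = 1
            groups[f"D{d:02d}"] = mu + rng.normal(0, math.sqrt(7.0), 37)
        ratio = ens.variance_ratio(table_from(groups), "M_cyto")
        # expected within / Var(device means) = 7 / (1 + 7/37) ~ 5.9
        assert 5.0 <= ratio <= 9.0

    def test_single_device_rejected(self):
        with pytest.raises(ValueError):
            ens.variance_ratio(table_from({"D0": [1, 2, 3]}), "M_cyto")


class TestAllocation:
    def test_no_region_variance_puts_one_region_per_device(self):
        model = ens.AllocationModel(sigma_d=0.0, sigma_m=2.0, k_total=60, overhead=2.0)
        n, m, se = ens.optimal_allocation(model)
        assert n == 1
        assert m == 20  # 60 // (1 + 2)

    def test_no_device_variance_ties_broken_toward_many_devices(self):
        model = ens.AllocationModel(sigma_d=1.0, sigma_m=0.0, k_total=24, overhead=0.0)
        n, m, se = ens.optimal_allocation(model)
        oracle = ens.allocation_oracle(model)
        assert (n, m) == (oracle[0], oracle[1])
        assert m * n == 24 and m == 24  # max devices among the SE ties

    def test_k_total_one_forces_single_observation(self):
        model = ens.AllocationModel(sigma_d=1.0, sigma_m=1.0, k_total=1, overhead=0.0)
        assert ens.allocation_oracle(model)[:2] == (1, 1)

    def test_zero_overhead_favors_pure_device_replication(self):
        model = ens.AllocationModel(sigma_d=2.0, sigma_m=1.0, k_total=100, overhead=0.0)
        n, m, _ = ens.allocation_oracle(model)
        assert n == 1 and m == 100

    def test_oracle_beats_every_feasible_allocation(self):
        model = ens.AllocationModel(sigma_d=2.6, sigma_m=1.0, k_total=200, overhead=5.0)
        n, m, se = ens.allocation_oracle(model)
        for mm in range(1, 33):
            nn = int(model.k_total / mm - model.overhead)
            if nn >= 1:
                assert se <= model.se(mm, nn) + 1e-12

    def test_variance_ratio_seven_case_matches_oracle(self):
        # sigma_d^2 / sigma_m^2 = 7 with per-device overhead 5
        model = ens.AllocationModel(
            sigma_d=math.sqrt(7.0), sigma_m=1.0, k_total=200, overhead=5.0
        )
        assert ens.optimal_allocation(model) == ens.allocation_oracle(model)

    def test_continuous_relaxation_brackets_integer_optimum(self):
        model = ens.AllocationModel(sigma_d=3.0, sigma_m=1.0, k_total=500, overhead=4.0)
        n_star = ens.optimal_regions_continuous(model)
        n, m, _ = ens.allocation_oracle(model)
        assert n_star == pytest.approx(3.0 * math.sqrt(4.0))
        # the integer optimum cannot be too far below the relaxation; budget
        # leftovers can push the integer n above it
        assert n >= math.floor(n_star) - 1

    def test_overhead_exhausting_budget_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            ens.AllocationModel(sigma_d=1.0, sigma_m=1.0, k_total=5, overhead=5.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        sigma_d=st.floats(0.0, 5.0),
        sigma_m=st.floats(0.0, 5.0),
        k_total=st.integers(2, 400),
        overhead=st.floats(0.0, 8.0),
    )
    def test_optimizer_equals_oracle(self, sigma_d, sigma_m, k_total, overhead):
        try:
            model = ens.AllocationModel(sigma_d, sigma_m, k_total, overhead)
        except ValueError:
            return
        try:
            fast = ens.optimal_allocation(model)
        except ValueError:
            with pytest.raises(ValueError):
                ens.allocation_oracle(model)
            return
        assert fast == ens.allocation_oracle(model)
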