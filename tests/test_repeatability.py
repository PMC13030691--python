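"""Repeatability statistics: worked examples, sums-of-squares oracles,
parameter recovery on synthetic cohorts, invariances."""

import math

import numpy as np
import pandas as pd
import pytest

from petrepeat import (
    CohortParams,
    InsufficientDataError,
    ParameterError,
    ValidationError,
    filter_by_volume,
    generate_paired_features,
    icc,
    limits_of_agreement,
    log_ratios,
    pairs_from_long,
    pairs_to_long,
    repeatability_table,
    variance_components,
    wcov,
)
from petrepeat.cohort import FEATURES
from petrepeat.repeatability import VarianceComponents
from conftest import make_pairs
from oracles import loop_icc_one_way, loop_icc_two_way, loop_variance_components


def random_small_samples(rng):
    """Random log-ratio table: <= 6 patients x <= 5 lesions each."""
    rows = []
    for p in range(rng.integers(2, 7)):
        for l in range(rng.integers(1, 6)):
            rows.append({"patient_id": f"P{p}", "lesion_id": f"P{p}-L{l}",
                         "log_ratio": rng.normal(0, 0.3)})
    return pd.DataFrame(rows)


class TestLogRatios:
    def test_examples(self):
        pairs = make_pairs([("A", "L1", 10.0, 10.0), ("A", "L2", 10.0, 20.0)])
        r = log_ratios(pairs, "suv_mean")["log_ratio"].to_numpy()
        assert r[0] == 0.0
        assert r[1] == pytest.approx(math.log(2.0))

    def test_loop_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.lognormal(1, 0.5, 50), rng.lognormal(1, 0.5, 50)
        pairs = pd.DataFrame(
            {"patient_id": ["P"] * 50, "lesion_id": range(50),
             **{f"{f}_test": a for f in FEATURES}, **{f"{f}_retest": b for f in FEATURES}}
        )
        got = log_ratios(pairs, "volume_cc")["log_ratio"].to_numpy()
        expected = [math.log(bb / aa) for aa, bb in zip(a, b)]
        np.testing.assert_allclose(got, expected, rtol=1e-14)

    def test_nonpositive_value_rejected_with_ids(self):
        pairs = make_pairs([("A", "L1", 10.0, 10.0), ("B", "L9", -1.0, 5.0)])
        with pytest.raises(ValidationError, match="B.*L9"):
            log_ratios(pairs, "suv_max")


class TestVarianceComponents:
    def test_all_identical(self):
        df = pd.DataFrame({"patient_id": list("AABB"), "lesion_id": range(4),
                           "log_ratio": [0.2] * 4})
        vc = variance_components(df)
        assert vc.d_bar == pytest.approx(0.2)
        assert vc.sigma == 0.0

    def test_hand_computed_two_patient_example(self):
        """Patient A r={0.1,0.1}, patient B r={-0.1,-0.1}: between-patient
        variance only."""
        df = pd.DataFrame({"patient_id": list("AABB"), "lesion_id": range(4),
                           "log_ratio": [0.1, 0.1, -0.1, -0.1]})
        vc = variance_components(df)
        assert vc.d_bar == pytest.approx(0.0)
        assert vc.ms_within == pytest.approx(0.0)
        assert vc.ms_between == pytest.approx(0.04)
        assert vc.m0 == pytest.approx(2.0)
        assert vc.var_between == pytest.approx(0.02)
        assert vc.sigma == pytest.approx(math.sqrt(0.02))

    def test_negative_between_variance_clamped(self):
        # equal patient means, large within-patient spread
        df = pd.DataFrame({"patient_id": list("AABB"), "lesion_id": range(4),
                           "log_ratio": [0.3, -0.3, 0.3, -0.3]})
        vc = variance_components(df)
        assert vc.ms_between < vc.ms_within
        assert vc.var_between == 0.0
        assert vc.sigma == pytest.approx(math.sqrt(vc.ms_within))

    def test_single_patient_falls_back_to_sample_sd(self):
        df = pd.DataFrame({"patient_id": ["A"] * 5, "lesion_id": range(5),
                           "log_ratio": [0.1, -0.2, 0.05, 0.0, 0.3]})
        vc = variance_components(df)
        assert vc.sigma == pytest.approx(np.std(df["log_ratio"], ddof=1))

    def test_all_singleton_patients_reduce_to_sample_sd(self):
        df = pd.DataFrame({"patient_id": list("ABCDE"), "lesion_id": range(5),
                           "log_ratio": [0.1, -0.2, 0.05, 0.0, 0.3]})
        vc = variance_components(df)
        assert vc.sigma == pytest.approx(np.std(df["log_ratio"], ddof=1))

    def test_insufficient_data(self):
        df = pd.DataFrame({"patient_id": ["A"], "lesion_id": [0], "log_ratio": [0.1]})
        with pytest.raises(InsufficientDataError):
            variance_components(df)

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df = random_small_samples(rng)
        vc = variance_components(df)
        d, msb, msw, m0, vb, sigma = loop_variance_components(
            df["patient_id"].tolist(), df["log_ratio"].tolist()
        )
        for got, exp in [(vc.d_bar, d), (vc.ms_between, msb), (vc.ms_within, msw),
                         (vc.m0, m0), (vc.var_between, vb), (vc.sigma, sigma)]:
            assert abs(got - exp) <= 1e-10


class TestLimitsOfAgreement:
    def test_degenerate(self):
        vc = VarianceComponents(0, 0, 0, 1, 0, 0, 1, 2)
        assert limits_of_agreement(vc) == (0.0, 0.0, 0.0)

    def test_back_transform_sigma_point_one(self):
        """d=0, sigma=0.1: bounds are 100(e^{+/-0.196}-1), asymmetric."""
        vc = VarianceComponents(0.0, 0, 0, 1, 0, 0.1, 1, 2)
        loa = limits_of_agreement(vc)
        assert loa.bias_pct == 0.0
        assert loa.loa_lower_pct == pytest.approx((math.exp(-0.196) - 1) * 100, abs=5e-3)
        assert loa.loa_upper_pct == pytest.approx((math.exp(0.196) - 1) * 100, abs=5e-3)
        assert loa.loa_lower_pct == pytest.approx(-17.80, abs=5e-3)
        assert loa.loa_upper_pct == pytest.approx(21.65, abs=5e-3)

    def test_bias_shifts_bounds_multiplicatively(self):
        base = limits_of_agreement(VarianceComponents(0.0, 0, 0, 1, 0, 0.1, 1, 2))
        shifted = limits_of_agreement(VarianceComponents(0.05, 0, 0, 1, 0, 0.1, 1, 2))
        f = math.exp(0.05)
        assert shifted.loa_lower_pct / 100 + 1 == pytest.approx(f * (base.loa_lower_pct / 100 + 1))
        assert shifted.loa_upper_pct / 100 + 1 == pytest.approx(f * (base.loa_upper_pct / 100 + 1))

    @pytest.mark.parametrize("seed", range(20))
    def test_lower_bound_above_minus_100(self, seed):
        rng = np.random.default_rng(seed)
        vc = VarianceComponents(rng.normal(0, 1), 0, 0, 1, 0, abs(rng.normal(0, 1)), 1, 2)
        loa = limits_of_agreement(vc)
        assert -100.0 < loa.loa_lower_pct <= loa.bias_pct <= loa.loa_upper_pct


class TestICC:
    def test_perfect_agreement(self):
        pairs = make_pairs([("A", i, v, v) for i, v in enumerate([1.0, 2.0, 5.0, 9.0])])
        assert icc(pairs, "suv_mean") == pytest.approx(1.0)

    def test_two_way_oracle_small_table(self):
        vals = [(3.0, 3.5), (7.0, 6.0), (12.0, 13.0), (5.0, 5.5)]
        pairs = make_pairs([("A", i, a, b) for i, (a, b) in enumerate(vals)])
        a = [v[0] for v in vals]
        b = [v[1] for v in vals]
        assert icc(pairs, "suv_max") == pytest.approx(loop_icc_two_way(a, b), abs=1e-12)
        assert icc(pairs, "suv_max", variant="one_way") == pytest.approx(
            loop_icc_one_way(a, b), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(10_000 + seed)
        n = rng.integers(3, 30)
        a = rng.lognormal(1.5, 0.6, n)
        b = a * rng.lognormal(0, 0.15, n)
        pairs = make_pairs([("A", i, a[i], b[i]) for i in range(n)])
        assert abs(icc(pairs, "suv_total") - loop_icc_two_way(a, b)) <= 1e-10
        assert abs(icc(pairs, "suv_total", variant="one_way") - loop_icc_one_way(a, b)) <= 1e-10

    def test_agrees_with_pingouin(self):
        """Independent cross-check against pingouin's ICC2 (absolute
        agreement, single rater) and ICC1."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n = 40
        a = rng.lognormal(1.5, 0.6, n)
        b = a * rng.lognormal(0, 0.2, n)
        pairs = make_pairs([("A", i, a[i], b[i]) for i in range(n)])
        long = pd.DataFrame({
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["t", "r"], n),
            "score": np.concatenate([a, b]),
        })
        res = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        assert icc(pairs, "suv_mean") == pytest.approx(
            res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0], abs=1e-9
        )
        assert icc(pairs, "suv_mean", variant="one_way") == pytest.approx(
            res.loc[res["Type"] == "ICC(1,1)", "ICC"].iloc[0], abs=1e-9
        )

    def test_permuted_retest_has_near_zero_icc(self):
        rng = np.random.default_rng(12)
        n = 5000
        a = rng.lognormal(1.5, 0.5, n)
        b = rng.permutation(a * rng.lognormal(0, 0.1, n))
        pairs = make_pairs([("A", i, a[i], b[i]) for i in range(n)])
        assert abs(icc(pairs, "volume_cc")) < 0.05

    def test_constant_subjects_undefined(self):
        pairs = make_pairs([("A", i, 3.0, 3.0) for i in range(4)])
        with pytest.raises(ValidationError):
            icc(pairs, "suv_mean")


class TestWCOV:
    def test_equal_pairs_zero(self):
        pairs = make_pairs([("A", i, v, v) for i, v in enumerate([1.0, 4.0, 2.5])])
        assert wcov(pairs, "suv_mean") == 0.0

    def test_single_pair_hand_computed(self):
        """(90, 110): within-pair SD 14.142, mean 100 -> wCOV 14.14%."""
        pairs = make_pairs([("A", 0, 90.0, 110.0)])
        assert wcov(pairs, "suv_max") == pytest.approx(100 * (20 / math.sqrt(2)) / 100, rel=1e-12)
        assert wcov(pairs, "suv_max") == pytest.approx(14.142, abs=1e-3)

    def test_monte_carlo_recovers_sigma_w(self):
        """Lognormal noise sigma_w=0.10, tau=0, N=5000: wCOV ~ 10%."""
        params = CohortParams(n_patients=250, lesions_per_patient_mean=20,
                              patient_bias_sd=0.0, lesion_noise_sd=0.10, seed=21)
        pairs, _ = generate_paired_features(params)
        assert wcov(pairs, "suv_mean") == pytest.approx(10.0, rel=0.10)

    def test_pooled_variant_on_equal_scale_data(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(0, 0.3, 200)
        b = a * rng.lognormal(0, 0.1, 200)
        pairs = make_pairs([("A", i, a[i], b[i]) for i in range(200)])
        pooled = wcov(pairs, "suv_mean", method="pooled")
        sd = np.abs(a - b) / math.sqrt(2)
        expected = 100 * math.sqrt(np.mean(sd**2)) / ((a + b) / 2).mean()
        assert pooled == pytest.approx(expected, rel=1e-12)


class TestVolumeFilter:
    def test_zero_threshold_vacuous(self, big_cohort_pairs):
        _, pairs, _ = big_cohort_pairs
        assert len(filter_by_volume(pairs, 0.0)) == len(pairs)

    def test_mean_volume_rule(self):
        pairs = make_pairs([("A", 0, 1.0, 1.0)])
        pairs["volume_cc_test"], pairs["volume_cc_retest"] = 0.9, 1.2
        assert len(filter_by_volume(pairs, 1.0)) == 1  # mean 1.05 > 1.0
        pairs["volume_cc_retest"] = 1.1  # mean 1.0, strict inequality drops it
        assert len(filter_by_volume(pairs, 1.0)) == 0

    def test_test_scan_statistic(self):
        pairs = make_pairs([("A", 0, 1.0, 1.0)])
        pairs["volume_cc_test"], pairs["volume_cc_retest"] = 0.9, 5.0
        assert len(filter_by_volume(pairs, 1.0, statistic="test")) == 0

    def test_counts_weakly_decreasing(self, big_cohort_pairs):
        _, pairs, _ = big_cohort_pairs
        counts = [len(filter_by_volume(pairs, t)) for t in (0.0, 1.0, 1.5)]
        assert counts[0] >= counts[1] >= counts[2]
        # direct-count oracle
        vol = (pairs["volume_cc_test"] + pairs["volume_cc_retest"]) / 2
        assert counts[1] == int((vol > 1.0).sum())

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            filter_by_volume(make_pairs([("A", 0, 1.0, 1.0)]), -0.5)


class TestRepeatabilityTable:
    def test_cardinality(self, small_params):
        pairs, _ = generate_paired_features(small_params)
        table = repeatability_table(pairs)
        assert len(table) == 12  # 4 features x 3 strata
        assert set(table["stratum"]) == {"all", ">1cc", ">1.5cc"}

    def test_zero_noise_cohort_degenerate_rows(self):
        params = CohortParams(n_patients=4, patient_bias_sd=0.0, lesion_noise_sd=0.0, seed=6)
        pairs, _ = generate_paired_features(params)
        table = repeatability_table(pairs)
        np.testing.assert_allclose(table["loa_lower_pct"], 0.0, atol=1e-9)
        np.testing.assert_allclose(table["loa_upper_pct"], 0.0, atol=1e-9)
        np.testing.assert_allclose(table["wcov_pct"], 0.0, atol=1e-9)
        np.testing.assert_allclose(table["icc"], 1.0, atol=1e-9)

    def test_rows_equal_direct_recomputation(self, small_params):
        pairs, _ = generate_paired_features(small_params)
        table = repeatability_table(pairs)
        strata = {"all": pairs, ">1cc": filter_by_volume(pairs, 1.0),
                  ">1.5cc": filter_by_volume(pairs, 1.5)}
        for row in table.itertuples():
            sub = strata[row.stratum]
            vc = variance_components(log_ratios(sub, row.feature))
            loa = limits_of_agreement(vc)
            assert row.n_lesions == len(sub)
            assert row.bias_pct == loa.bias_pct
            assert row.loa_lower_pct == loa.loa_lower_pct
            assert row.loa_upper_pct == loa.loa_upper_pct
            assert row.icc == icc(sub, row.feature)
            assert row.wcov_pct == wcov(sub, row.feature)

    def test_scale_equivariance(self, small_params):
        """Multiplying every feature value by a constant leaves the log-ratio
        metrics, ICC and wCOV unchanged."""
        pairs, _ = generate_paired_features(small_params)
        scaled = pairs.copy()
        for f in FEATURES:
            scaled[f"{f}_test"] *= 37.0
            scaled[f"{f}_retest"] *= 37.0
        scaled["volume_cc_test"] = pairs["volume_cc_test"]  # keep strata identical
        scaled["volume_cc_retest"] = pairs["volume_cc_retest"]
        a = repeatability_table(pairs, features=("suv_max", "suv_mean", "suv_total"))
        b = repeatability_table(scaled, features=("suv_max", "suv_mean", "suv_total"))
        pd.testing.assert_frame_equal(a, b, rtol=1e-9)

    def test_tiny_stratum_skipped_with_warning(self, caplog):
        pairs = make_pairs([("A", 0, 2.0, 2.1), ("A", 1, 3.0, 2.9), ("B", 2, 4.0, 4.2)])
        pairs["volume_cc_test"] = [0.5, 0.6, 0.7]
        pairs["volume_cc_retest"] = [0.5, 0.6, 0.7]
        with caplog.at_level("WARNING"):
            table = repeatability_table(pairs, features=("suv_max",), thresholds_cc=(1.0,))
        assert set(table["stratum"]) == {"all"}
        assert "skipped" in caplog.text


class TestParameterRecovery:
    @pytest.mark.parametrize("tau", [0.0, 0.05, 0.15])
    @pytest.mark.parametrize("sigma_w", [0.0, 0.05, 0.15])
    def test_sigma_and_wcov_recovery(self, tau, sigma_w):
        """The estimator recovers sigma = sqrt(tau^2 + 2 sigma_w^2); the RMS
        wCOV estimates 100 sqrt((tau^2 + 2 sigma_w^2)/2), which is 100 sigma_w
        when there is no patient-level bias.

        When tau dominates, the effective sample size for sigma is the number
        of patients, so estimates are averaged over three replicate ~5000-
        lesion cohorts of 500 patients each.
        """
        sigmas, wcovs = [], []
        for rep in range(3):
            params = CohortParams(n_patients=500, lesions_per_patient_mean=10,
                                  patient_bias_sd=tau, lesion_noise_sd=sigma_w,
                                  seed=int(10_000 * tau + 1000 * sigma_w) + rep)
            pairs, _ = generate_paired_features(params)
            assert len(pairs) > 4000
            sigmas.append(variance_components(log_ratios(pairs, "suv_mean")).sigma)
            wcovs.append(wcov(pairs, "suv_mean"))
        sigma_hat, wcov_hat = np.mean(sigmas), np.mean(wcovs)
        target = math.sqrt(tau**2 + 2 * sigma_w**2)
        if target == 0.0:
            assert sigma_hat == 0.0
            assert wcov_hat == 0.0
        else:
            assert sigma_hat == pytest.approx(target, rel=0.10)
            assert wcov_hat == pytest.approx(100 * target / math.sqrt(2), rel=0.10)
        if tau == 0.0 and sigma_w > 0.0:
            assert wcov_hat == pytest.approx(100 * sigma_w, rel=0.10)

    def test_coverage_of_loa_interval(self, big_cohort_pairs):
        """~95% of log-ratios fall inside d_bar +/- 1.96 sigma at N~5000."""
        _, pairs, _ = big_cohort_pairs
        r = log_ratios(pairs, "suv_mean")
        vc = variance_components(r)
        inside = np.abs(r["log_ratio"] - vc.d_bar) <= 1.96 * vc.sigma
        assert inside.mean() == pytest.approx(0.95, abs=0.02)

    def test_icc_recovery_against_variance_ratio(self):
        """Between-lesion log SD 0.5, sigma_w 0.1, tau 0: the observed ICC on
        raw values approaches the lognormal between/total variance ratio."""
        params = CohortParams(n_patients=250, lesions_per_patient_mean=20,
                              log_uptake_sd=0.5, patient_bias_sd=0.0,
                              lesion_noise_sd=0.1, seed=17)
        pairs, _ = generate_paired_features(params)
        s2, w2 = 0.5**2, 0.1**2
        var_total = math.exp(s2 + w2) * (math.exp(s2 + w2) - 1)  # x exp(2 mu), cancels
        var_between = math.exp(w2) * math.exp(s2) * (math.exp(s2) - 1)
        predicted = var_between / var_total
        assert icc(pairs, "suv_mean") == pytest.approx(predicted, abs=0.03)


class TestLongWideRoundTrip:
    def test_round_trip(self, small_params):
        pairs, _ = generate_paired_features(small_params)
        back = pairs_from_long(pairs_to_long(pairs))
        a = pairs.sort_values("lesion_id").reset_index(drop=True)
        b = back.sort_values("lesion_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b[a.columns], check_like=True)

    def test_unpaired_lesions_dropped(self):
        long = pd.DataFrame({
            "patient_id": ["A", "A", "A"],
            "lesion_id": ["L1", "L1", "L2"],
            "timepoint": ["test", "retest", "test"],
            "suv_max": [2.0, 2.1, 9.0], "suv_mean": [1.0, 1.1, 4.0],
            "suv_total": [2.0, 2.2, 36.0], "volume_cc": [2.0, 2.0, 9.0],
        })
        pairs = pairs_from_long(long)
        assert list(pairs["lesion_id"]) == ["L1"]
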