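"""High-expressor threshold, association, and the KS-trimmed normal core."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ctcohort import (
    chi_square_2x2,
    classify_and_associate,
    high_expression_threshold,
    iterative_normal_core,
    sd_distance,
)
from ctcohort.subgroup import SubgroupError


class TestThreshold:
    def test_constant_controls(self):
        assert high_expression_threshold([2.0] * 6) == pytest.approx(2.0)

    def test_hand_computation_linear_quantiles(self):
        # values 1..8: median 4.5, Q1 2.75, Q3 6.25 -> T = 4.5 + 1.25*3.5
        t = high_expression_threshold(np.arange(1.0, 9.0))
        assert t == pytest.approx(8.875)

    def test_weibull_convention_differs(self):
        x = np.arange(1.0, 9.0)
        t_lin = high_expression_threshold(x, quantile_method="linear")
        t_spss = high_expression_threshold(x, quantile_method="weibull")
        assert t_spss != t_lin  # SPSS-style (n+1)p hinge is wider here
        assert t_spss == pytest.approx(4.5 + 1.25 * (6.75 - 2.25))

    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=30),
           st.floats(0.1, 5), st.floats(-10, 10))
    def test_affine_equivariance(self, values, a, b):
        t = high_expression_threshold(values)
        t2 = high_expression_threshold([a * v + b for v in values])
        assert t2 == pytest.approx(a * t + b, rel=1e-9, abs=1e-7)

    def test_threshold_at_least_median(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        assert high_expression_threshold(x) >= np.median(x)

    def test_too_few_controls_rejected(self):
        with pytest.raises(SubgroupError):
            high_expression_threshold([1.0, 2.0, 3.0])


class TestClassifyAndAssociate:
    def test_equal_prevalence_balanced_groups(self):
        control = np.r_[np.zeros(8), 5.0, 5.0]
        case = control.copy()
        res = classify_and_associate({"control": control, "case": case},
                                     threshold=1.0, case_group="case",
                                     control_group="control")
        assert res.risk_ratio == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0)

    def test_risk_ratio_hand_arithmetic(self):
        control = np.r_[np.ones(9) * 2.0, np.zeros(62)]   # 9/71 above T=1
        case = np.r_[np.ones(22) * 2.0, np.zeros(50)]     # 22/72 above T=1
        res = classify_and_associate({"control": control, "case": case},
                                     threshold=1.0, case_group="case",
                                     control_group="control")
        assert res.risk_ratio == pytest.approx((22 / 72) / (9 / 71))
        assert res.risk_ratio == pytest.approx(2.41, abs=0.005)

    def test_chi2_consistent_with_group_stats(self):
        rng = np.random.default_rng(1)
        control = rng.normal(0, 1, 50)
        case = rng.normal(0.8, 1, 50)
        t = 0.5
        res = classify_and_associate({"control": control, "case": case},
                                     threshold=t, case_group="case",
                                     control_group="control")
        fc = int((case > t).sum())
        f0 = int((control > t).sum())
        oracle = chi_square_2x2([[fc, 50 - fc], [f0, 50 - f0]])
        assert res.chi2 == pytest.approx(oracle.statistic, abs=1e-12)
        assert res.p == pytest.approx(oracle.p_value, abs=1e-12)

    def test_no_high_expressors_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="no sample"):
            res = classify_and_associate(
                {"control": np.zeros(5), "case": np.zeros(5)},
                threshold=1.0, case_group="case", control_group="control")
        assert res.chi2 is None and res.risk_ratio is None

    def test_zero_flagged_controls_infinite_risk_ratio(self):
        with pytest.warns(UserWarning, match="infinite"):
            res = classify_and_associate(
                {"control": np.zeros(10), "case": np.r_[np.ones(4) * 2, np.zeros(6)]},
                threshold=1.0, case_group="case", control_group="control")
        assert np.isinf(res.risk_ratio)
        assert res.chi2 is not None  # association still computed

    def test_missing_group_rejected(self):
        with pytest.raises(SubgroupError, match="case"):
            classify_and_associate({"control": np.ones(5)}, 0.5,
                                   case_group="case", control_group="control")


class TestIterativeNormalCore:
    def test_clean_normal_samples_rarely_trimmed(self):
        """Under the Lilliefors null at n=60 most seeds need <= 1 removal."""
        few_removals = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            core = iterative_normal_core(rng.normal(10, 2, 60))
            if len(core.removed) <= 1:
                few_removals += 1
        assert few_removals >= 160  # >= 80% of seeds

    def test_planted_outliers_removed_in_descending_order(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 60)
        planted = np.array([8.0, 8.5, 9.0, 9.5, 10.0])
        core = iterative_normal_core(np.r_[base, planted])
        assert core.removed == sorted(planted, reverse=True)
        assert core.n == 60
        assert core.ks_p > 0.05 and core.converged

    def test_never_removes_below_current_mean(self):
        rng = np.random.default_rng(8)
        x = np.r_[rng.normal(0, 1, 40), rng.exponential(4, 10) + 3]
        core = iterative_normal_core(x)
        # removal order is strictly non-increasing (always the current max)
        assert all(a >= b for a, b in zip(core.removed, core.removed[1:]))
        if core.removed:
            assert min(core.removed) >= core.mean

    def test_constant_values_error(self):
        with pytest.raises(SubgroupError, match="zero SD"):
            iterative_normal_core([4.0] * 10)

    def test_nonconvergence_reported(self):
        # far-separated bimodal halves still reject when trimming hits min_n
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0, 0.1, 7), rng.normal(100, 0.1, 7)]
        core = iterative_normal_core(x, min_n=10)
        assert not core.converged
        assert core.n == 10

    def test_summary_matches_surviving_set(self):
        rng = np.random.default_rng(9)
        x = np.r_[rng.normal(0, 1, 50), [25.0]]
        core = iterative_normal_core(x)
        survivors = np.sort(x)[: 51 - len(core.removed)]
        assert core.mean == pytest.approx(survivors.mean())
        assert core.sd == pytest.approx(survivors.std(ddof=1))


class TestSdDistance:
    def test_published_core_arithmetic(self):
        # flagged controls 3.053 vs trimmed core 0.8919 +/- 0.4308 -> ~5 SD
        assert sd_distance([3.053], (0.8919, 0.4308)) == pytest.approx(5.016, abs=0.005)

    def test_flagged_at_core_mean_is_zero(self):
        assert sd_distance([1.5, 0.5], (1.0, 0.3)) == pytest.approx(0.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(10)
        flagged = rng.normal(5, 1, 8)
        mean, sd = 1.0, 0.4
        d = sd_distance(flagged, (mean, sd))
        a, b = 2.5, -3.0
        d2 = sd_distance(a * flagged + b, (a * mean + b, a * sd))
        assert d2 == pytest.approx(d)

    def test_zero_core_sd_rejected(self):
        with pytest.raises(SubgroupError):
            sd_distance([2.0], (1.0, 0.0))


class TestCalibrationAndPower:
    def test_type_one_flag_rate_matches_gaussian_tail(self):
        """On pure normal data the flagged fraction approaches
        P(Z > 1.25 * IQR_z), the tail beyond median + 1.25*IQR."""
        iqr_z = stats.norm.ppf(0.75) - stats.norm.ppf(0.25)
        expected = stats.norm.sf(1.25 * iqr_z)
        rng = np.random.default_rng(11)
        fracs = []
        for _ in range(300):
            control = rng.normal(0, 1, 71)
            case = rng.normal(0, 1, 72)
            t = high_expression_threshold(control)
            fracs.append(((case > t).sum() + (control > t).sum()) / 143)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.015)

    def test_association_type_one_error_near_alpha(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            control = rng.normal(0, 1, 71)
            case = rng.normal(0, 1, 72)
            t = high_expression_threshold(control)
            fc, f0 = int((case > t).sum()), int((control > t).sum())
            if fc + f0 == 0:
                continue
            try:
                res = chi_square_2x2([[fc, 72 - fc], [f0, 71 - f0]])
            except Exception:
                continue
            if res.p_value <= 0.05:
                rejections += 1
        assert 0.005 <= rejections / n_rep <= 0.12

    def test_planted_subgroup_power_and_sensitivity(self):
        """With a 5-SD shift and 13%/32% prevalence at n=71/72, flagged
        samples recover the subpopulation and the association usually rejects."""
        from ctcohort import (GeneSpec, default_cohort_spec, generate_cohort,
                              generate_expression)
        cohort = generate_cohort(default_cohort_spec(seed=13))
        is_control = (cohort["group"] == "control").to_numpy()
        gene = GeneSpec("G", core_sd=0.5, subpop_shift_sd=5.0,
                        subpop_prevalence={"control": 0.13, "schizophrenia": 0.32})
        sens, rejected = [], 0
        n_rep = 100
        for seed in range(n_rep):
            expr = generate_expression(cohort, gene, seed=seed)
            rq = expr["rq"].to_numpy()
            truth = expr["is_subpop"].to_numpy()
            t = high_expression_threshold(rq[is_control])
            flags = rq > t
            if truth.sum():
                sens.append((flags & truth).sum() / truth.sum())
            fc = int(flags[~is_control].sum())
            f0 = int(flags[is_control].sum())
            res = chi_square_2x2([[fc, 72 - fc], [f0, 71 - f0]])
            if res.p_value <= 0.05:
                rejected += 1
        assert np.mean(sens) > 0.95
        assert rejected / n_rep > 0.5

    def test_planted_flag_fraction_within_binomial_ci(self):
        """At n=500 per group every planted member is recovered (a 5-SD shift
        clears the threshold), and the flagged fraction matches the planted
        prevalence plus the analytic null tail of the log-normal core beyond
        median + 1.25*IQR, within the binomial 95% CI."""
        from ctcohort import (CohortSpec, GeneSpec, GroupCovariates,
                              generate_cohort, generate_expression)
        n = 500
        spec = CohortSpec(
            n_per_group={"control": n, "case": n},
            covariate_params={g: GroupCovariates() for g in ("control", "case")},
            seed=14,
        )
        cohort = generate_cohort(spec)
        p = 0.2
        core_sd = 0.5
        gene = GeneSpec("G", core_sd=core_sd, subpop_shift_sd=5.0,
                        subpop_prevalence={"control": 0.0, "case": p})
        expr = generate_expression(cohort, gene, seed=15)
        rq = expr["rq"].to_numpy()
        truth = expr["is_subpop"].to_numpy()
        is_case = (cohort["group"] == "case").to_numpy()
        t = high_expression_threshold(rq[~is_case])
        flags = rq > t
        assert flags[truth].all()  # full sensitivity at 5 core-SD separation
        # null tail of the rq-scale (log-normal) core above median + 1.25*IQR
        sigma = core_sd * np.log(2.0)
        q = stats.norm.ppf(0.75) * sigma
        t_null = 1.0 + 1.25 * (np.exp(q) - np.exp(-q))
        null_tail = stats.norm.sf(np.log(t_null) / sigma)
        expected = p + (1 - p) * null_tail
        frac = flags[is_case].mean()
        half_width = 1.96 * np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) <= half_width + 0.01  # + threshold noise
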