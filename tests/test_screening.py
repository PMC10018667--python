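"""Confidence-limit action limits, screening decisions and correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dosescreen.errors import CohortError, ConfigurationError
from dosescreen.metrics import Criterion, CriterionId, MetricComparison
from dosescreen.presets import PRESETS, sample_cohort_comparisons
from dosescreen.screening import (
    ActionLimitTable,
    Rounding,
    Scale,
    confidence_limit,
    confidence_limit_from_moments,
    correlate,
    derive_action_limits,
    screen_case,
)


def comp(name, pct, tid=None, tps=50.0):
    return MetricComparison(
        CriterionId(name, tid), tps, tps * (1 + pct / 100.0), pct
    )


def gamma_comp(pass_rate):
    return MetricComparison(CriterionId(Criterion.GAMMA_3D), 100.0, pass_rate, None)


class TestConfidenceLimit:
    def test_symmetric_pair(self):
        al = confidence_limit([-1.0, 1.0], Rounding.NONE)
        assert al.cohort_mean == pytest.approx(0.0)
        assert al.cohort_sd == pytest.approx(math.sqrt(2))
        assert al.cl_raw == pytest.approx(2.7719, abs=1e-3)

    def test_identical_values_reduce_to_their_magnitude(self):
        al = confidence_limit([-4.2] * 10, Rounding.NONE)
        assert al.cl_raw == pytest.approx(4.2)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(CohortError):
            confidence_limit([1.0])

    @given(
        st.lists(st.floats(-30, 30), min_size=2, max_size=50),
    )
    def test_cl_dominates_mean_and_sd(self, values):
        al = confidence_limit(values, Rounding.NONE)
        assert al.cl_raw >= abs(al.cohort_mean) - 1e-12
        assert al.cl_raw >= 1.96 * al.cohort_sd - 1e-12

    @pytest.mark.parametrize(
        "x,decimals,expected",
        [(15.96, 0, 16.0), (2.5, 0, 3.0), (3.44, 1, 3.4), (28.496, 1, 28.5), (6.2252, 1, 6.2)],
    )
    def test_rounding_half_away_from_zero(self, x, decimals, expected):
        r = Rounding.INT if decimals == 0 else Rounding.ONE_DECIMAL
        assert confidence_limit_from_moments(x, 0.0, r).limit == expected


class TestDeriveActionLimits:
    def test_perfect_cohort_yields_zero_limits(self):
        cohort = [
            [comp(Criterion.PTV_MEAN, 0.0, 1), gamma_comp(100.0)] for _ in range(5)
        ]
        table = derive_action_limits(cohort)
        assert table["PTV_MEAN"].limit == 0.0
        assert table["GAMMA_3D"].limit == 0.0
        assert table["GAMMA_3D"].min_pass_rate == 100.0

    def test_gamma_limit_lives_on_the_failure_scale(self):
        cohort = [
            [gamma_comp(pr), comp(Criterion.PTV_MEAN, 0.0, 1)]
            for pr in (90.0, 95.0, 85.0, 92.0)
        ]
        table = derive_action_limits(cohort)
        fails = [10.0, 5.0, 15.0, 8.0]
        expected = np.mean(fails) + 1.96 * np.std(fails, ddof=1)
        assert table["GAMMA_3D"].cl_raw == pytest.approx(expected)
        assert table["GAMMA_3D"].scale == Scale.GAMMA_FAIL

    def test_uniform_simplification_overrides_dose_criteria_only(self):
        cohort = sample_cohort_comparisons("AXB_LUNG_LIKE", 30, seed=3)
        table = derive_action_limits(cohort, uniform_simplification=3.0)
        for name, al in table.limits.items():
            if al.scale == Scale.PCT_DIFF:
                assert al.limit == 3.0 and al.simplified
            else:
                assert not al.simplified

    def test_missing_criterion_names_offender(self):
        cohort = [
            [comp(Criterion.PTV_MEAN, 1.0, 1), gamma_comp(99.0)],
            [gamma_comp(98.0)],
        ]
        with pytest.raises(CohortError, match="case 1"):
            derive_action_limits(cohort)

    def test_limits_table_json_round_trip(self):
        cohort = sample_cohort_comparisons("MLSRS_LIKE", 30, seed=1)
        table = derive_action_limits(cohort, site="MLSRS")
        back = ActionLimitTable.from_json(table.to_json())
        assert set(back.limits) == set(table.limits)
        for k in table.limits:
            assert back[k].limit == table[k].limit
            assert back[k].cl_raw == pytest.approx(table[k].cl_raw)


def simple_limits(dose_limit=5.0, gamma_limit=6.2):
    return ActionLimitTable(
        {
            "PTV_D95": confidence_limit_from_moments(0, dose_limit / 1.96,
                                                     criterion="PTV_D95"),
            "PTV_MEAN": confidence_limit_from_moments(0, dose_limit / 1.96,
                                                      criterion="PTV_MEAN"),
            "GAMMA_3D": confidence_limit_from_moments(
                0, gamma_limit / 1.96, Rounding.ONE_DECIMAL,
                scale=Scale.GAMMA_FAIL, criterion="GAMMA_3D"),
        }
    )


class TestScreenCase:
    def test_all_within_limits_not_flagged(self):
        comps = [comp(Criterion.PTV_D95, -3.0, 1), gamma_comp(97.0)]
        d = screen_case(comps, simple_limits())
        assert not d.flagged and d.flagged_targets == []

    def test_exceeding_target_is_flagged_and_listed(self):
        comps = [
            comp(Criterion.PTV_D95, -6.1, 2),
            comp(Criterion.PTV_D95, -1.0, 1),
            gamma_comp(99.0),
        ]
        d = screen_case(comps, simple_limits(dose_limit=5.0))
        assert d.flagged
        assert d.flagged_targets == [2]

    def test_boundary_value_passes_inclusively(self):
        comps = [comp(Criterion.PTV_MEAN, 5.0, 1), gamma_comp(100.0 - 6.2)]
        d = screen_case(comps, simple_limits(dose_limit=5.0, gamma_limit=6.2))
        assert not d.flagged

    def test_gamma_below_minimum_pass_rate_flags(self):
        d = screen_case([gamma_comp(90.0)], simple_limits(gamma_limit=6.2))
        assert d.flagged

    def test_missing_limit_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            screen_case([comp(Criterion.ISOCENTRE_DOSE, 0.0)], simple_limits())

    def test_loosening_limits_is_monotone(self):
        comps = [comp(Criterion.PTV_D95, -6.1, 1), comp(Criterion.PTV_MEAN, -2.0, 1),
                 gamma_comp(96.0)]
        tight = screen_case(comps, simple_limits(dose_limit=5.0))
        loose = screen_case(comps, simple_limits(dose_limit=7.0))
        assert tight.flagged and not loose.flagged
        for a, b in zip(tight.checks, loose.checks):
            assert b.passed or not a.passed  # loosening never fails a passer

    def test_expected_flag_rate_near_five_percent_at_the_cl_boundary(self):
        # limits derived from one zero-mean Normal cohort should flag ~5% of
        # an i.i.d. replicate cohort (the 95% CL construction)
        rng = np.random.default_rng(2024)
        sd = 2.0
        train = rng.normal(0.0, sd, 5000)
        al = confidence_limit(train, Rounding.NONE)
        replicate = rng.normal(0.0, sd, 20000)
        rate = np.mean(np.abs(replicate) > al.cl_raw)
        assert rate == pytest.approx(0.05, abs=0.012)


class TestCorrelate:
    def frame(self, values_by_crit):
        rows = []
        for crit, vals in values_by_crit.items():
            for i, v in enumerate(vals):
                rows.append({"case_id": f"c{i}", "criterion": crit, "target_id": 1,
                             "pct_diff": v})
        return pd.DataFrame(rows)

    def test_self_correlation_is_one(self):
        a = self.frame({"PTV_MEAN": [1.0, 2.0, 3.5, -1.0], "PTV_D95": [0.5, 2.2, -3.0, 1.0]})
        rep = correlate(a, a)
        assert all(r == pytest.approx(1.0) for r in rep.per_criterion.values())
        assert rep.mean_r == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        a = self.frame({"PTV_MEAN": [1.0, 2.0, 3.0]})
        b = self.frame({"PTV_MEAN": [-1.0, -2.0, -3.0]})
        assert correlate(a, b).per_criterion["PTV_MEAN"] == pytest.approx(-1.0)

    def test_exact_linear_relation(self):
        a = self.frame({"PTV_MEAN": [1.0, 2.0, 3.0]})
        b = self.frame({"PTV_MEAN": [2.0, 4.0, 6.0]})
        assert correlate(a, b).per_criterion["PTV_MEAN"] == pytest.approx(1.0)

    def test_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = self.frame({"PTV_MEAN": list(x)})
        b = self.frame({"PTV_MEAN": list(y)})
        r_ab = correlate(a, b).per_criterion["PTV_MEAN"]
        r_ba = correlate(b, a).per_criterion["PTV_MEAN"]
        b_affine = self.frame({"PTV_MEAN": list(3.0 * y + 7.0)})
        r_affine = correlate(a, b_affine).per_criterion["PTV_MEAN"]
        assert r_ab == pytest.approx(r_ba)
        assert r_affine == pytest.approx(r_ab)

    def test_zero_variance_reported_as_undefined(self):
        a = self.frame({"PTV_MEAN": [1.0, 1.0, 1.0]})
        b = self.frame({"PTV_MEAN": [1.0, 2.0, 3.0]})
        rep = correlate(a, b)
        assert rep.per_criterion["PTV_MEAN"] is None
        assert rep.mean_r is None

    def test_too_few_pairs_rejected(self):
        a = self.frame({"PTV_MEAN": [1.0, 2.0]})
        with pytest.raises(CohortError):
            correlate(a, a)


class TestStatisticalCohorts:
    def test_sampler_is_seed_reproducible(self):
        a = sample_cohort_comparisons("AAA_LUNG_LIKE", 10, seed=4)
        b = sample_cohort_comparisons("AAA_LUNG_LIKE", 10, seed=4)
        assert all(
            x.secondary_value == y.secondary_value
            for ca, cb in zip(a, b) for x, y in zip(ca, cb)
        )

    @pytest.mark.parametrize("preset_name", sorted(PRESETS))
    def test_moments_recovered_at_large_n(self, preset_name):
        preset = PRESETS[preset_name]
        cohort = sample_cohort_comparisons(preset, 2000, seed=11)
        table = derive_action_limits(cohort)
        for crit, (mu, sd) in preset.dose_stats.items():
            al = table[crit.value]
            assert al.cl_raw == pytest.approx(abs(mu) + 1.96 * sd, abs=1.0)
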