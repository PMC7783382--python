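"""Outcome estimators: odds ratios, NNT, imputation, sensitivity, counts."""

import itertools
import math

import numpy as np
import pytest

from t2titrate.analysis import (
    adherence_exacerbation_cox,
    analysis_frame,
    exacerbation_models,
    number_needed_to_treat,
    primary_analysis,
    refused_ocs_analysis,
    sensitivity_bounds,
    trial_report,
    unadjusted_odds_ratio,
)
from t2titrate.cohort import CohortConfig
from t2titrate.conduct import TrialConfig, run_trial


class TestUnadjustedOddsRatio:
    @pytest.mark.parametrize(
        "a,b,c,d,expected",
        [
            (31, 70, 1, 19, 8.41),   # per-protocol dose-reduction table
            (33, 92, 2, 33, 5.92),   # uncontrolled-asthma subgroup
            (57, 44, 7, 9, 1.67),    # refused OCS initiation
            (5, 5, 5, 5, 1.0),
        ],
    )
    def test_printed_tables(self, a, b, c, d, expected):
        est = unadjusted_odds_ratio(a, b, c, d)
        assert est.point == pytest.approx(expected, abs=0.005)
        assert est.lo <= est.point <= est.hi

    def test_matches_exhaustive_cross_product_oracle(self):
        # all 2x2 tables with margins <= 20 (stride-sampled for runtime)
        for a, b, c, d in itertools.product(range(0, 21, 4), repeat=4):
            est = unadjusted_odds_ratio(a, b, c, d)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                assert math.isnan(est.point)
                assert "undefined_margin" in est.flags
                continue
            aa, bb, cc, dd = (
                (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
                if 0 in (a, b, c, d)
                else (a, b, c, d)
            )
            assert est.point == pytest.approx((aa * dd) / (bb * cc))

    def test_zero_cell_haldane_flag(self):
        est = unadjusted_odds_ratio(5, 5, 0, 10)
        assert "haldane_corrected" in est.flags
        assert np.isfinite(est.point)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            unadjusted_odds_ratio(-1, 5, 5, 5)


class TestNNT:
    @pytest.mark.parametrize(
        "p1,p0,expected",
        [(0.307, 0.050, 4), (1.0, 0.0, 1), (0.30, 0.10, 5)],
    )
    def test_point_estimates(self, p1, p0, expected):
        assert number_needed_to_treat(p1, p0).nnt == expected

    def test_pp_interval_lower_bound(self):
        est = number_needed_to_treat(31 / 101, 1 / 20, 101, 20)
        assert est.nnt == 4
        assert est.lo == 3
        assert est.hi >= est.nnt

    def test_non_positive_difference_flagged(self):
        est = number_needed_to_treat(0.1, 0.2)
        assert not est.defined
        assert est.nnt is None


class TestPrimaryAnalysis:
    def test_no_missing_data_equals_complete_case(self):
        cfg = TrialConfig(cohort=CohortConfig(n=60), withdrawal_hazard=0.0)
        ds = run_trial(cfg, seed=21)
        mi = primary_analysis(ds, "itt", imputation=True, seed=1)
        cc = primary_analysis(ds, "itt", imputation=False)
        assert "no_missing_outcomes" in mi.flags
        assert mi.point == pytest.approx(cc.point, rel=1e-9)

    def test_mice_pooled_or_near_complete_case(self, full_trial):
        mi = primary_analysis(full_trial, "itt", m=10, cycles=5, seed=2)
        cc = primary_analysis(full_trial, "itt", imputation=False)
        assert "mice_pooled" in mi.flags
        # imputation shifts the estimate only modestly under ~10% missingness
        assert math.log(mi.point) == pytest.approx(math.log(cc.point), abs=0.5)

    def test_interval_brackets_point(self, full_trial):
        est = primary_analysis(full_trial, "itt", imputation=False)
        assert est.lo <= est.point <= est.hi
        assert est.adjusted


class TestSensitivityBounds:
    def test_zero_withdrawals_collapse_to_complete_case(self):
        cfg = TrialConfig(cohort=CohortConfig(n=60), withdrawal_hazard=0.0)
        ds = run_trial(cfg, seed=22)
        best, worst = sensitivity_bounds(ds, "itt")
        cc = primary_analysis(ds, "itt", imputation=False)
        assert best.point == pytest.approx(cc.point, rel=1e-9)
        assert worst.point == pytest.approx(cc.point, rel=1e-9)

    def test_proportion_bracketing(self, full_trial):
        # per-arm observed proportions lie between the all-reduced and
        # none-reduced completions, by construction
        df = analysis_frame(full_trial, "itt")
        for arm in (0, 1):
            g = df[df["trt"] == arm]
            obs = g["dose_reduced"].dropna()
            p_cc = obs.mean()
            p_best = (obs.sum() + g["dose_reduced"].isna().sum()) / len(g)
            p_worst = obs.sum() / len(g)
            assert p_worst <= p_cc <= p_best


class TestExacerbationModels:
    def test_rate_conservation(self, full_trial):
        df = analysis_frame(full_trial, "itt")
        ex = exacerbation_models(full_trial, "itt")
        for arm, code in (("biomarker", 1), ("control", 0)):
            g = df[df["trt"] == code]
            rate = ex["annual_rate"][arm]
            assert rate * g["exposure_years"].sum() == pytest.approx(
                g["n_exacs"].sum()
            )

    def test_doubling_counts_doubles_rate(self, full_trial):
        import pandas as pd

        ex = exacerbation_models(full_trial, "itt")
        doubled = full_trial.__class__(
            patients=full_trial.patients,
            visits=full_trial.visits,
            events=pd.concat([full_trial.events] * 2, ignore_index=True),
        )
        ex2 = exacerbation_models(doubled, "itt")
        for arm in ("biomarker", "control"):
            assert ex2["annual_rate"][arm] == pytest.approx(
                2 * ex["annual_rate"][arm]
            )

    def test_rate_ratio_and_hazard_ratio_fit(self, full_trial):
        ex = exacerbation_models(full_trial, "itt")
        rr = ex["exacerbation rate ratio"]
        hr = ex["time to first exacerbation HR"]
        assert rr.lo <= rr.point <= rr.hi
        assert 0.2 < rr.point < 5
        assert hr.lo <= hr.point <= hr.hi

    def test_extra_events_for_non_followers_raise_their_hazard(self, full_trial):
        import pandas as pd

        from t2titrate.populations import count_deviations

        # parameter-recovery direction check: graft earlier extra events onto
        # non-followers and the within-arm hazard ratio must exceed 1
        dev = count_deviations(full_trial)
        bio = full_trial.patients[full_trial.patients["arm"] == "biomarker"]
        non_follow = bio.loc[dev.reindex(bio["patient_id"]).to_numpy() > 0, "patient_id"]
        extra = pd.DataFrame(
            {
                "patient_id": non_follow,
                "week": 2.0,
                "criterion": "rescue_ocs_3d",
            }
        )
        boosted = full_trial.__class__(
            patients=full_trial.patients,
            visits=full_trial.visits,
            events=pd.concat([full_trial.events, extra], ignore_index=True),
        )
        est = adherence_exacerbation_cox(boosted, arm="biomarker")
        assert est.point > 1.0


def test_refused_ocs_analysis_runs(full_trial):
    est = refused_ocs_analysis(full_trial, "itt")
    assert est.n_active + est.n_control > 0


def test_trial_report_shape(full_trial):
    report = trial_report(full_trial, "itt", m=5)
    assert {"estimand", "population"}.issubset(report.columns)
    assert (report["population"] == "itt").all()
    assert len(report) >= 10
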