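"""Unit and property tests for the two per-visit scoring algorithms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2titrate.scoring import (
    EOS_CUTS,
    FENO_CUTS,
    PERIOSTIN_CUTS,
    Advisory,
    BiomarkerPanel,
    Direction,
    advisory_from_score,
    band_score,
    score_biomarker_panel,
    score_symptom_risk,
    score_visit_table,
)

EPS = np.finfo(float).eps


class TestCompositeScore:
    @pytest.mark.parametrize(
        "feno,eos,per,subs,composite",
        [
            (21, 200, 52.8, (1, 1, 1), 1),   # trial baseline medians
            (10, 100, 30, (0, 0, 0), 0),
            (40, 100, 40, (2, 0, 0), 1),     # sum 2 -> average 0.667 -> 1
            (31, 301, 56, (2, 2, 2), 2),
            (14.9, 149, 44.9, (0, 0, 0), 0),
        ],
    )
    def test_banding_and_rounding(self, feno, eos, per, subs, composite):
        cs = score_biomarker_panel(BiomarkerPanel(feno, eos, per))
        assert (cs.sub_feno, cs.sub_eos, cs.sub_periostin) == subs
        assert cs.composite == composite
        assert not cs.defaulted

    @pytest.mark.parametrize(
        "cuts,value,expected",
        # both cut-points belong to the middle band; a hair either side flips
        [
            (c, v, e)
            for c in (FENO_CUTS, EOS_CUTS, PERIOSTIN_CUTS)
            for v, e in [
                (c[0], 1),
                (c[1], 1),
                (c[0] * (1 - 4 * EPS), 0),
                (c[0] * (1 + 4 * EPS), 1),
                (c[1] * (1 - 4 * EPS), 1),
                (c[1] * (1 + 4 * EPS), 2),
            ]
        ],
    )
    def test_band_boundaries(self, cuts, value, expected):
        assert band_score(value, cuts) == expected

    def test_all_27_subscore_triples_match_rounded_average(self):
        # independent oracle: enumerate subscores directly and compare the
        # composite with round-half-up of sum/3
        reps = {0: 10.0, 1: 20.0, 2: 40.0}  # FENO values hitting each band
        reps_e = {0: 100.0, 1: 200.0, 2: 400.0}
        reps_p = {0: 40.0, 1: 50.0, 2: 60.0}
        for sf in (0, 1, 2):
            for se in (0, 1, 2):
                for sp in (0, 1, 2):
                    cs = score_biomarker_panel(
                        BiomarkerPanel(reps[sf], reps_e[se], reps_p[sp])
                    )
                    expected = math.floor((sf + se + sp) / 3 + 0.5)
                    assert cs.composite == expected
                    assert cs.composite in (0, 1, 2)

    def test_missing_component_defaults_to_maintain(self):
        cs = score_biomarker_panel(BiomarkerPanel(21, None, 52.8))
        assert cs.defaulted
        assert cs.composite == 1
        adv = advisory_from_score(cs.composite, "biomarker", cs.defaulted)
        assert adv.direction is Direction.MAINTAIN
        assert adv.source == "default"

    def test_negative_value_names_component(self):
        with pytest.raises(ValueError, match="periostin"):
            BiomarkerPanel(21, 200, -1)

    def test_eosinophil_unit_heuristic(self):
        with pytest.warns(UserWarning, match="10\\^9"):
            panel = BiomarkerPanel(21, 0.2, 52.8)
        assert panel.eos == pytest.approx(200.0)

    @given(
        feno=st.floats(0, 200),
        eos=st.floats(20, 2000),
        per=st.floats(0, 150),
        bump=st.floats(0, 50),
        component=st.sampled_from(["feno", "eos", "periostin"]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_each_component(self, feno, eos, per, bump, component):
        base = dict(feno=feno, eos=eos, periostin=per)
        raised = dict(base)
        raised[component] += bump
        lo = score_biomarker_panel(BiomarkerPanel(**base))
        hi = score_biomarker_panel(BiomarkerPanel(**raised))
        sub = f"sub_{component}" if component != "periostin" else "sub_periostin"
        assert getattr(hi, sub) >= getattr(lo, sub)
        assert hi.composite >= lo.composite


class TestSymptomRisk:
    @pytest.mark.parametrize(
        "acq,base,exac,score",
        [
            (2.6, 1.5, False, 2),   # >=1.5 with >=1-point worsening
            (0.8, 0.8, False, 0),
            (1.2, 1.2, False, 1),
            (0.5, 0.5, True, 2),    # exacerbation dominates
            (1.7, 1.0, False, 1),   # high but <1 change
            (0.99, 0.0, False, 0),
            (1.0, 1.0, False, 1),
        ],
    )
    def test_examples(self, acq, base, exac, score):
        assert score_symptom_risk(acq, base, exac).score == score

    @given(acq=st.floats(0, 6), base=st.floats(0, 6))
    @settings(max_examples=100, derandomize=True)
    def test_exacerbation_always_scores_two(self, acq, base):
        assert score_symptom_risk(acq, base, True).score == 2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_symptom_risk(6.5, 2.0, False)


class TestAdvisory:
    @pytest.mark.parametrize(
        "score,direction",
        [(0, Direction.DECREASE), (1, Direction.MAINTAIN), (2, Direction.INCREASE)],
    )
    def test_total_mapping(self, score, direction):
        assert advisory_from_score(score, "biomarker").direction is direction

    def test_defaulted_must_maintain(self):
        with pytest.raises(ValueError):
            Advisory(Direction.DECREASE, "default", defaulted=True)

    def test_invalid_score(self):
        with pytest.raises(ValueError):
            advisory_from_score(3, "biomarker")


def test_score_visit_table_appends_columns():
    import pandas as pd

    df = pd.DataFrame(
        {
            "patient_id": [1, 2],
            "week": [0, 0],
            "feno_ppb": [21.0, np.nan],
            "eos_per_ul": [200.0, 100.0],
            "periostin_ng_ml": [52.8, 30.0],
            "acq7": [2.6, 0.8],
            "acq7_baseline": [1.5, 0.8],
            "exac_since_last": [False, False],
        }
    )
    scored = score_visit_table(df)
    assert list(scored["composite"]) == [1, 1]
    assert list(scored["defaulted"]) == [False, True]
    assert list(scored["advisory"]) == ["maintain", "maintain"]
    assert list(scored["symptom_risk"]) == [2, 0]


def test_score_visit_table_threshold_overrides():
    import pandas as pd

    df = pd.DataFrame(
        {
            "feno_ppb": [21.0],
            "eos_per_ul": [200.0],
            "periostin_ng_ml": [52.8],
        }
    )
    scored = score_visit_table(
        df, thresholds={"feno_cuts": (10, 20), "eos_cuts": (250, 500)}
    )
    assert scored.loc[0, "sub_feno"] == 2
    assert scored.loc[0, "sub_eos"] == 0
    with pytest.raises(ValueError, match="threshold"):
        score_visit_table(df, thresholds={"feno": (10, 20)})
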