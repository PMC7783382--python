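"""Trial conduct: randomisation, the visit loop, masking, determinism."""

import numpy as np
import pandas as pd
import pytest

from t2titrate.cohort import CohortConfig
from t2titrate.conduct import (
    ADVISORY_WEEKS,
    VISIT_WEEKS,
    TrialConfig,
    conduct_visit,
    randomize,
    run_trial,
)
from t2titrate.scoring import BiomarkerPanel


def _patients(n, acq_high=None, rescue_high=None, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "patient_id": range(n),
            "acq_high": acq_high if acq_high is not None else rng.random(n) < 0.5,
            "rescue_high": rescue_high if rescue_high is not None else rng.random(n) < 0.5,
        }
    )


class TestRandomize:
    def test_single_stratum_block_is_exact(self):
        pts = _patients(10, acq_high=[True] * 10, rescue_high=[False] * 10)
        arm = randomize(pts, seed=3)
        assert (arm == "biomarker").sum() == 8
        assert (arm == "control").sum() == 2

    def test_empty(self):
        assert len(randomize(_patients(0))) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_301_patients_biomarker_arm_within_truncation_bound(self, seed):
        # at most 4 truncated blocks (one per stratum), each off by at most
        # +/- 4 from the 4:1 expectation of its truncated length
        pts = _patients(301, seed=seed)
        arm = randomize(pts, seed=seed)
        n_bio = (arm == "biomarker").sum()
        assert 236 <= n_bio <= 244

    def test_every_complete_block_within_stratum_is_8_2(self):
        pts = _patients(60, acq_high=[False] * 60, rescue_high=[True] * 60)
        arm = randomize(pts, seed=9)
        for start in range(0, 60, 10):
            block = arm.iloc[start : start + 10]
            assert (block == "biomarker").sum() == 8

    def test_reproducible_from_seed(self):
        pts = _patients(100, seed=5)
        assert randomize(pts, seed=17).equals(randomize(pts, seed=17))

    def test_invalid_block_ratio(self):
        with pytest.raises(ValueError):
            randomize(_patients(10), ratio=(3, 1), block_size=10)


def _one_patient(arm="biomarker", refuses_ocs=False, step=4):
    return pd.Series(
        {
            "patient_id": 0,
            "arm": arm,
            "acq7_baseline": 2.0,
            "refuses_ocs": refuses_ocs,
            "withdrawn_at": np.nan,
        }
    ), step


class TestConductVisit:
    def setup_method(self):
        self.cfg = TrialConfig()

    def _visit(self, patient, step, panel, week=8, acq=2.0, exacs=0,
               exac_active=False, rng=None):
        return conduct_visit(
            patient,
            week,
            {
                "panel": panel,
                "acq7": acq,
                "exacs_since_last": exacs,
                "exac_active": exac_active,
            },
            step,
            self.cfg,
            rng or np.random.default_rng(0),
            visit_index=week // 8,
        )

    def test_biomarker_arm_low_composite_decrease_followed(self):
        patient, step = _one_patient()
        rec = self._visit(patient, step, BiomarkerPanel(10, 100, 30))
        assert rec["advisory"] == "decrease"
        assert rec["composite"] == 0
        if rec["followed"]:
            assert rec["step_after"] == step - 1

    def test_control_arm_ignores_biomarkers(self):
        patient, step = _one_patient(arm="control")
        # composite would say decrease; symptom score 1 says maintain
        rec = self._visit(patient, step, BiomarkerPanel(10, 100, 30), acq=1.2)
        assert rec["composite"] == 0
        assert rec["advisory"] == "maintain"
        assert rec["step_after"] == step

    def test_ocs_refuser_never_starts_ocs(self):
        patient, _ = _one_patient(refuses_ocs=True)
        ceiling_ics = self.cfg.cohort.ladder.locate(2000, 0)
        for trial_seed in range(10):
            rec = self._visit(
                patient, ceiling_ics, BiomarkerPanel(40, 400, 60),
                rng=np.random.default_rng(trial_seed),
            )
            assert rec["advisory"] == "increase"
            assert not rec["followed"]
            assert rec["refused_ocs_initiation"]
            assert rec["ocs_after"] == 0.0

    def test_exacerbation_defers_dose_change(self):
        patient, step = _one_patient()
        rec = self._visit(
            patient, step, BiomarkerPanel(10, 100, 30), exacs=1, exac_active=True
        )
        assert rec["deferred"]
        assert rec["step_after"] == step

    def test_masking_message_identical_across_arms(self):
        for arm in ("biomarker", "control"):
            patient, step = _one_patient(arm=arm)
            rec = self._visit(patient, step, BiomarkerPanel(21, 200, 52.8))
            assert rec["masking_message"] == "maintain"

    def test_visit_after_withdrawal_rejected(self):
        patient, step = _one_patient()
        patient["withdrawn_at"] = 8.0
        with pytest.raises(RuntimeError, match="withdrawal"):
            self._visit(patient, step, BiomarkerPanel(21, 200, 52.8), week=16)

    def test_no_advisory_at_final_assessment(self):
        patient, step = _one_patient()
        rec = self._visit(patient, step, BiomarkerPanel(10, 100, 30), week=48)
        assert rec["advisory"] == ""
        assert rec["step_after"] == step


class TestRunTrial:
    def test_no_withdrawal_gives_full_schedule(self):
        cfg = TrialConfig(cohort=CohortConfig(n=40), withdrawal_hazard=0.0)
        ds = run_trial(cfg, seed=2)
        counts = ds.visits.groupby("patient_id")["week"].count()
        assert (counts == len(VISIT_WEEKS)).all()
        assert ds.patients["withdrawn_at"].isna().all()

    def test_byte_identical_reruns(self, small_config):
        a = run_trial(small_config, seed=11)
        b = run_trial(small_config, seed=11)
        assert a.checksum() == b.checksum()

    def test_different_seed_differs(self, small_config):
        a = run_trial(small_config, seed=11)
        b = run_trial(small_config, seed=12)
        assert a.checksum() != b.checksum()

    def test_no_dose_change_at_deferred_visits(self, small_trial):
        deferred = small_trial.visits[small_trial.visits["deferred"]]
        assert (deferred["step_after"] == deferred["step_before"]).all()

    def test_advisory_conservation(self, small_trial):
        v = small_trial.visits
        issued = v[v["advisory"] != ""]
        assert issued["followed"].sum() <= len(issued)
        # every attended pre-final visit carries an advisory and the masking
        # message; structure is identical across arms
        pre_final = v[v["week"] < 48]
        assert (pre_final["advisory"] != "").all()
        assert (pre_final["masking_message"] == "maintain").all()

    def test_withdrawal_truncates_but_keeps_visits(self, full_trial):
        wd = full_trial.patients.dropna(subset=["withdrawn_at"])
        assert len(wd) > 0
        for _, p in wd.head(10).iterrows():
            weeks = full_trial.visits.loc[
                full_trial.visits["patient_id"] == p["patient_id"], "week"
            ]
            assert (weeks < p["withdrawn_at"]).all()
            assert weeks.is_monotonic_increasing

    def test_states_stay_on_ladder(self, small_trial, small_config):
        ladder = small_config.cohort.ladder
        for _, row in small_trial.visits.iterrows():
            assert ladder.locate(row["ics_after"], row["ocs_after"]) == row["step_after"]

    def test_deterministic_control_dose_path_under_full_adherence(self):
        # with adherence forced and no withdrawal, the control arm's dose
        # trajectory is a function of its ACQ-7/exacerbation path alone
        cfg = TrialConfig(
            cohort=CohortConfig(n=30, refuse_ocs_frac=0.0),
            p_follow_maintain=1.0,
            p_follow_change_biomarker=1.0,
            p_follow_change_control=1.0,
            adherence_decay=0.0,
            centre_adherence_sd=0.0,
            withdrawal_hazard=0.0,
        )
        ds = run_trial(cfg, seed=3)
        ctl = ds.visits.merge(
            ds.patients[["patient_id", "arm", "step_baseline"]], on="patient_id"
        )
        ctl = ctl[ctl["arm"] == "control"].sort_values(["patient_id", "week"])
        ladder = cfg.cohort.ladder
        for pid, grp in ctl.groupby("patient_id"):
            step = int(grp["step_baseline"].iloc[0])
            for _, row in grp.iterrows():
                if row["week"] < 48 and not row["deferred"]:
                    move = {0: -1, 1: 0, 2: +1}[int(row["symptom_risk"])]
                    step = int(np.clip(step + move, 0, ladder.ceiling))
                assert row["step_after"] == step
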