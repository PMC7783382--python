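"""Analysis-population construction and the primary-outcome classifier.

The trial's estimand populations:

* **ITT** — every randomised patient who attended at least one follow-up
  visit;
* **PP** — completed every visit and followed every treatment advisory,
  except that an unfollowed *decrease* while already at the ladder floor,
  and any deviation by a patient with clinically low cortisol, are exempt;
* **relaxed PP(k)** — at most ``k`` protocol deviations (unfollowed
  advisories or missed visits), k ∈ {1, 2};
* **uncontrolled** — the ITT subset with baseline ACQ-7 ≥ 1.5.

These nest: PP ⊆ relaxed_PP(1) ⊆ relaxed_PP(2) ⊆ ITT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conduct import VISIT_WEEKS, TrialDataset
from .ladder import TreatmentState

__all__ = ["PopulationSpec", "build_population", "classify_dose_reduction", "count_deviations"]


@dataclass(frozen=True)
class PopulationSpec:
    """Which analysis population to construct."""

    kind: str  # "itt" | "pp" | "relaxed_pp" | "uncontrolled"
    k: int = 0  # allowed deviations, for relaxed_pp

    def __post_init__(self) -> None:
        if self.kind not in {"itt", "pp", "relaxed_pp", "uncontrolled"}:
            raise ValueError(f"unknown population kind {self.kind!r}")
        if self.kind == "relaxed_pp" and self.k not in (1, 2):
            raise ValueError("relaxed_pp allows k = 1 or 2")

    @classmethod
    def parse(cls, name: str) -> "PopulationSpec":
        """Parse 'itt' | 'pp' | 'pp1' | 'pp2' | 'uncontrolled'."""
        name = name.lower()
        if name in {"itt", "pp", "uncontrolled"}:
            return cls(name)
        if name in {"pp1", "pp2"}:
            return cls("relaxed_pp", int(name[-1]))
        raise ValueError(f"unknown population {name!r}")


def classify_dose_reduction(
    baseline: TreatmentState | int, final: TreatmentState | int
) -> bool:
    """True iff the final dose sits strictly below baseline on the ladder.

    Because OCS tiers are ordered above ICS tiers, a lower ladder step is
    exactly "OCS decreased, or OCS unchanged and ICS decreased"; any OCS
    increase lands above regardless of ICS.
    """
    b = baseline.step if isinstance(baseline, TreatmentState) else int(baseline)
    f = final.step if isinstance(final, TreatmentState) else int(final)
    return f < b


def count_deviations(dataset: TrialDataset) -> pd.Series:
    """Protocol deviations per patient: unfollowed advisories + missed visits.

    Exemptions (not deviations): deferred advisories, an unfollowed decrease
    while at the ladder floor, and every deviation by a low-cortisol patient.
    Scheduled visits after withdrawal count as missed.
    """
    visits = dataset.visits
    patients = dataset.patients.set_index("patient_id")
    dev = pd.Series(0, index=patients.index, dtype=int)

    if len(visits):
        adv = visits[(visits["advisory"] != "") & ~visits["deferred"]]
        unfollowed = adv[~adv["followed"].astype(bool)]
        floor_exempt = (unfollowed["advisory"] == "decrease") & (
            unfollowed["step_before"] == 0
        )
        unfollowed = unfollowed[~floor_exempt]
        dev = dev.add(
            unfollowed.groupby("patient_id").size(), fill_value=0
        ).astype(int)
        attended = visits.groupby("patient_id")["week"].nunique()
    else:
        attended = pd.Series(dtype=int)
    n_scheduled = len(VISIT_WEEKS)
    missed = (n_scheduled - attended.reindex(patients.index).fillna(0)).astype(int)
    dev += missed
    dev[patients["low_cortisol"].astype(bool)] = 0
    return dev


def build_population(dataset: TrialDataset, spec: PopulationSpec) -> pd.Index:
    """Patient ids belonging to the requested analysis population."""
    patients = dataset.patients.set_index("patient_id")
    visits = dataset.visits
    if len(visits):
        followup = visits[visits["week"] > 0].groupby("patient_id").size()
    else:
        followup = pd.Series(dtype=int)
    itt = patients.index[followup.reindex(patients.index).fillna(0) > 0]

    if spec.kind == "itt":
        return itt
    if spec.kind == "uncontrolled":
        return itt[patients.loc[itt, "acq7_baseline"] >= 1.5]
    dev = count_deviations(dataset)
    k = 0 if spec.kind == "pp" else spec.k
    return itt[dev.loc[itt] <= k]
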