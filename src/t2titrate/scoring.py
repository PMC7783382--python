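"""Per-visit treatment-adjustment scoring.

Two algorithms drive corticosteroid dose advisories in the trial:

* the composite type-2 biomarker score, built from FENO (ppb), blood
  eosinophil count (cells/µL) and serum periostin (ng/mL), each banded
  into a 0/1/2 subscore and combined as the rounded average of their sum;
* the symptom–risk score, built from the ACQ-7 questionnaire and recent
  severe-exacerbation history.

Both produce a decision score in {0, 1, 2} that maps onto an advisory:
0 → decrease treatment, 1 → maintain, 2 → increase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import pandas as pd

__all__ = [
    "BiomarkerPanel",
    "CompositeScore",
    "SymptomRiskScore",
    "Direction",
    "Advisory",
    "FENO_CUTS",
    "EOS_CUTS",
    "PERIOSTIN_CUTS",
    "band_score",
    "score_biomarker_panel",
    "score_symptom_risk",
    "advisory_from_score",
    "score_visit_table",
]

#: Band cut-points (lower, upper); value < lower → 0, lower ≤ value ≤ upper → 1,
#: value > upper → 2.
FENO_CUTS = (15.0, 30.0)       # ppb
EOS_CUTS = (150.0, 300.0)      # cells/µL
PERIOSTIN_CUTS = (45.0, 55.0)  # ng/mL

#: Eosinophil inputs below this are taken to be 10⁹ cells/L and rescaled
#: to cells/µL (×1000). Counts this low are not physiological in either unit
#: for a severe-asthma population reported in cells/µL.
EOS_UNIT_THRESHOLD = 20.0


class Direction(str, Enum):
    """Advisory direction on the treatment ladder."""

    DECREASE = "decrease"
    MAINTAIN = "maintain"
    INCREASE = "increase"


@dataclass(frozen=True)
class BiomarkerPanel:
    """One visit's type-2 biomarker measurements.

    Parameters
    ----------
    feno : float or None
        Fractional exhaled nitric oxide, ppb. ``None``/NaN marks a missing
        measurement.
    eos : float or None
        Blood eosinophil count, cells/µL. Values below
        :data:`EOS_UNIT_THRESHOLD` are interpreted as 10⁹ cells/L and
        converted (×1000) with a warning.
    periostin : float or None
        Serum periostin, ng/mL.
    """

    feno: Optional[float] = None
    eos: Optional[float] = None
    periostin: Optional[float] = None

    def __post_init__(self) -> None:
        feno = _clean("feno", self.feno)
        eos = _clean("eos", self.eos)
        periostin = _clean("periostin", self.periostin)
        if eos is not None and eos < EOS_UNIT_THRESHOLD:
            warnings.warn(
                f"eosinophil count {eos:g} < {EOS_UNIT_THRESHOLD:g}: "
                "interpreting as 10^9 cells/L and converting to cells/uL",
                stacklevel=3,
            )
            eos *= 1000.0
        object.__setattr__(self, "feno", feno)
        object.__setattr__(self, "eos", eos)
        object.__setattr__(self, "periostin", periostin)

    @property
    def missing(self) -> tuple[str, ...]:
        """Names of the components that were not measured."""
        return tuple(
            name
            for name in ("feno", "eos", "periostin")
            if getattr(self, name) is None
        )


def _clean(name: str, value: Optional[float]) -> Optional[float]:
    if value is None:
        return None
    value = float(value)
    if math.isnan(value):
        return None
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return value


@dataclass(frozen=True)
class CompositeScore:
    """Composite biomarker score for one visit.

    ``composite`` is the rounded average of the three subscores
    (round-half-up on ``sum/3``; attainable thirds never land on .5, so any
    conventional rounding rule agrees).  When any component is missing the
    score is ``defaulted``: the advisory is forced to "maintain" and
    ``composite`` is reported as 1.
    """

    sub_feno: Optional[int]
    sub_eos: Optional[int]
    sub_periostin: Optional[int]
    defaulted: bool

    @property
    def sum(self) -> Optional[int]:
        subs = (self.sub_feno, self.sub_eos, self.sub_periostin)
        if any(s is None for s in subs):
            return None
        return sum(subs)  # type: ignore[arg-type]

    @property
    def composite(self) -> int:
        if self.defaulted:
            return 1
        return int(math.floor(self.sum / 3 + 0.5))


@dataclass(frozen=True)
class SymptomRiskScore:
    """Symptom–risk score for one visit (control-arm algorithm)."""

    acq7: float
    acq7_baseline: float
    exac_since_last: bool
    score: int = field(init=False)

    def __post_init__(self) -> None:
        for name in ("acq7", "acq7_baseline"):
            v = getattr(self, name)
            if not (0.0 <= v <= 6.0):
                raise ValueError(f"{name} must lie in [0, 6], got {v!r}")
        if self.exac_since_last or (
            self.acq7 >= 1.5 and self.acq7 - self.acq7_baseline >= 1.0
        ):
            score = 2
        elif self.acq7 < 1.0:
            score = 0
        else:
            score = 1
        object.__setattr__(self, "score", score)


@dataclass(frozen=True)
class Advisory:
    """A per-visit treatment advisory."""

    direction: Direction
    source: str  # "biomarker", "symptom_risk" or "default"
    defaulted: bool = False

    def __post_init__(self) -> None:
        if self.defaulted and self.direction is not Direction.MAINTAIN:
            raise ValueError("a defaulted advisory must be 'maintain'")


def band_score(value: float, cuts: tuple[float, float]) -> int:
    """Band a biomarker value into a 0/1/2 subscore.

    The middle band is inclusive of both cut-points: ``value < cuts[0]`` → 0,
    ``cuts[0] <= value <= cuts[1]`` → 1, ``value > cuts[1]`` → 2.
    """
    lo, hi = cuts
    if value < lo:
        return 0
    if value <= hi:
        return 1
    return 2


def score_biomarker_panel(
    panel: BiomarkerPanel,
    feno_cuts: tuple[float, float] = FENO_CUTS,
    eos_cuts: tuple[float, float] = EOS_CUTS,
    periostin_cuts: tuple[float, float] = PERIOSTIN_CUTS,
) -> CompositeScore:
    """Score a biomarker panel with the composite type-2 algorithm.

    Each available component is banded into a subscore; the composite is
    the rounded average of the subscore sum. If any component is missing
    the result is flagged ``defaulted`` and reads as a maintain advisory.
    The default cut-points are the trial's protocol values; they can be
    overridden for threshold-sensitivity work.

    Examples
    --------
    >>> score_biomarker_panel(BiomarkerPanel(21, 200, 52.8)).composite
    1
    """
    subs = {}
    for name, cuts in (
        ("feno", feno_cuts),
        ("eos", eos_cuts),
        ("periostin", periostin_cuts),
    ):
        value = getattr(panel, name)
        subs[name] = None if value is None else band_score(value, cuts)
    defaulted = any(v is None for v in subs.values())
    return CompositeScore(
        sub_feno=subs["feno"],
        sub_eos=subs["eos"],
        sub_periostin=subs["periostin"],
        defaulted=defaulted,
    )


def score_symptom_risk(
    acq7: float, acq7_baseline: float, exac_since_last: bool
) -> SymptomRiskScore:
    """Score current symptoms and recent exacerbation history.

    Score 2 when a severe exacerbation occurred since the last visit, or when
    ACQ-7 ≥ 1.5 with a worsening of ≥ 1 point from the randomisation
    baseline; score 0 when ACQ-7 < 1.0 with no exacerbation; score 1
    otherwise.
    """
    return SymptomRiskScore(acq7, acq7_baseline, exac_since_last)


def advisory_from_score(score: int, source: str, defaulted: bool = False) -> Advisory:
    """Map a decision score to an advisory: 0→decrease, 1→maintain, 2→increase."""
    if defaulted:
        return Advisory(Direction.MAINTAIN, source="default", defaulted=True)
    if score not in (0, 1, 2):
        raise ValueError(f"decision score must be 0, 1 or 2, got {score!r}")
    direction = (Direction.DECREASE, Direction.MAINTAIN, Direction.INCREASE)[score]
    return Advisory(direction, source=source)


def score_visit_table(
    visits: pd.DataFrame, thresholds: dict | None = None
) -> pd.DataFrame:
    """Score a visit-level table and append subscore/advisory columns.

    Expects columns ``feno_ppb``, ``eos_per_ul``, ``periostin_ng_ml``,
    ``acq7``, ``exac_since_last`` and (for the symptom–risk baseline)
    ``acq7_baseline``; appends ``sub_feno``, ``sub_eos``, ``sub_periostin``,
    ``composite``, ``symptom_risk``, ``advisory`` (composite-driven) and
    ``defaulted``.  ``thresholds`` may override any of ``feno_cuts``,
    ``eos_cuts`` and ``periostin_cuts`` as (lower, upper) pairs.
    """
    thresholds = thresholds or {}
    cut_kw = {
        k: tuple(thresholds[k])
        for k in ("feno_cuts", "eos_cuts", "periostin_cuts")
        if k in thresholds
    }
    unknown = set(thresholds) - {"feno_cuts", "eos_cuts", "periostin_cuts"}
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    out = visits.copy()
    comps, subs_f, subs_e, subs_p, advs, defaults, symp = [], [], [], [], [], [], []
    for row in out.itertuples(index=False):
        panel = BiomarkerPanel(
            getattr(row, "feno_ppb", None),
            getattr(row, "eos_per_ul", None),
            getattr(row, "periostin_ng_ml", None),
        )
        cs = score_biomarker_panel(panel, **cut_kw)
        subs_f.append(cs.sub_feno)
        subs_e.append(cs.sub_eos)
        subs_p.append(cs.sub_periostin)
        comps.append(cs.composite)
        defaults.append(cs.defaulted)
        advs.append(
            advisory_from_score(cs.composite, "biomarker", cs.defaulted).direction.value
        )
        if hasattr(row, "acq7") and hasattr(row, "acq7_baseline"):
            symp.append(
                score_symptom_risk(
                    row.acq7, row.acq7_baseline, bool(row.exac_since_last)
                ).score
            )
        else:
            symp.append(None)
    out["sub_feno"] = subs_f
    out["sub_eos"] = subs_e
    out["sub_periostin"] = subs_p
    out["composite"] = comps
    out["symptom_risk"] = symp
    out["advisory"] = advs
    out["defaulted"] = defaults
    return out
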