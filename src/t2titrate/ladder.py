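"""The corticosteroid treatment ladder.

Doses are expressed as (ICS in beclometasone-dipropionate-equivalent µg/day,
maintenance oral prednisolone mg/day).  The ladder orders dose pairs by total
corticosteroid intensity: ICS titrates first, and maintenance OCS tiers sit
on top of the maximum ICS dose.  A "decrease" advisory therefore withdraws
OCS before ICS, and an "increase" escalates ICS before initiating OCS —
standard step-down/step-up practice in severe asthma clinics.

The trial protocol's exact dose steps are not published; the default ladder
is a documented stand-in chosen so that the trial's typical baseline
(ICS 2000 µg/day) sits one step above 1000 µg/day, matching the observed
median reduction of 1000 µg among patients who stepped down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .scoring import Advisory, Direction

__all__ = [
    "TreatmentState",
    "Ladder",
    "DEFAULT_LADDER",
    "apply_advisory",
]

#: Default ICS titration steps (BDP-equivalent µg/day); one step below the
#: typical 2000 µg baseline is 1000 µg, the observed median reduction.
DEFAULT_ICS_STEPS = (200, 500, 800, 1000, 2000)
#: Default maintenance OCS tiers (prednisolone mg/day), on top of maximal ICS.
DEFAULT_OCS_TIERS = (5, 10, 15, 20, 30, 40)


@dataclass(frozen=True)
class TreatmentState:
    """A position on the treatment ladder.

    Attributes
    ----------
    ics_bdp : float
        Inhaled corticosteroid dose, BDP-equivalent µg/day.
    ocs_mg : float
        Maintenance oral prednisolone, mg/day (0 when not on OCS).
    step : int
        Index of this dose pair on the ladder (0 = floor).
    at_floor, at_ceiling : bool
        Set when a decrease (increase) advisory was clamped at the ladder
        boundary and the state returned unchanged.
    """

    ics_bdp: float
    ocs_mg: float
    step: int
    at_floor: bool = False
    at_ceiling: bool = False


class Ladder:
    """An ordered sequence of (ICS µg/day, OCS mg/day) dose pairs.

    Steps are ordered from lowest to highest total corticosteroid intensity.
    OCS tiers may only appear above the maximum ICS tier, and adjacent steps
    must differ in exactly one of the two doses; both invariants are checked
    at construction.
    """

    def __init__(self, steps: Sequence[tuple[float, float]]):
        steps = [(float(i), float(o)) for i, o in steps]
        if len(steps) < 2:
            raise ValueError("a ladder needs at least two steps")
        max_ics = max(i for i, _ in steps)
        prev = None
        for k, (ics, ocs) in enumerate(steps):
            if ics < 0 or ocs < 0:
                raise ValueError(f"negative dose at step {k}")
            if ocs > 0 and ics != max_ics:
                raise ValueError(
                    f"step {k}: OCS tiers must sit on the maximum ICS dose"
                )
            if prev is not None:
                d_ics = ics != prev[0]
                d_ocs = ocs != prev[1]
                if d_ics == d_ocs:
                    raise ValueError(
                        f"steps {k - 1}->{k} must change exactly one dose"
                    )
                if ics < prev[0] or ocs < prev[1]:
                    raise ValueError(f"steps {k - 1}->{k} not increasing")
            prev = (ics, ocs)
        self._steps = tuple(steps)

    @classmethod
    def default(cls) -> "Ladder":
        steps = [(ics, 0.0) for ics in DEFAULT_ICS_STEPS]
        steps += [(DEFAULT_ICS_STEPS[-1], ocs) for ocs in DEFAULT_OCS_TIERS]
        return cls(steps)

    def __len__(self) -> int:
        return len(self._steps)

    def __getitem__(self, step: int) -> tuple[float, float]:
        return self._steps[step]

    @property
    def steps(self) -> tuple[tuple[float, float], ...]:
        return self._steps

    @property
    def floor(self) -> int:
        return 0

    @property
    def ceiling(self) -> int:
        return len(self._steps) - 1

    def state(self, step: int) -> TreatmentState:
        """The :class:`TreatmentState` at a ladder index."""
        ics, ocs = self._steps[step]
        return TreatmentState(ics, ocs, step)

    def locate(self, ics_bdp: float, ocs_mg: float) -> int:
        """Ladder index of a dose pair; raises if the pair is off-ladder."""
        try:
            return self._steps.index((float(ics_bdp), float(ocs_mg)))
        except ValueError:
            raise ValueError(
                f"dose pair (ICS {ics_bdp}, OCS {ocs_mg}) is not on the ladder"
            ) from None

    def validate(self, state: TreatmentState) -> None:
        if not (0 <= state.step < len(self._steps)):
            raise ValueError(f"step {state.step} outside ladder")
        if self._steps[state.step] != (state.ics_bdp, state.ocs_mg):
            raise ValueError(
                f"state (ICS {state.ics_bdp}, OCS {state.ocs_mg}) does not "
                f"match ladder step {state.step} {self._steps[state.step]}"
            )


DEFAULT_LADDER = Ladder.default()


def apply_advisory(
    state: TreatmentState,
    advisory: Advisory,
    followed: bool,
    ladder: Ladder = DEFAULT_LADDER,
) -> TreatmentState:
    """Apply an advisory to a treatment state on the ladder.

    Unfollowed and maintain advisories leave the state unchanged. A followed
    decrease moves one step down (withdrawing OCS before ICS by ladder
    construction); a followed increase moves one step up. At the ladder
    floor a decrease returns the state unchanged with ``at_floor`` set, and
    symmetrically ``at_ceiling`` at the top.
    """
    ladder.validate(state)
    if not followed or advisory.direction is Direction.MAINTAIN:
        return ladder.state(state.step)
    if advisory.direction is Direction.DECREASE:
        if state.step == ladder.floor:
            s = ladder.state(state.step)
            return TreatmentState(s.ics_bdp, s.ocs_mg, s.step, at_floor=True)
        return ladder.state(state.step - 1)
    if state.step == ladder.ceiling:
        s = ladder.state(state.step)
        return TreatmentState(s.ics_bdp, s.ocs_mg, s.step, at_ceiling=True)
    return ladder.state(state.step + 1)
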