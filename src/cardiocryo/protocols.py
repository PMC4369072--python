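"""Freeze-thaw protocol catalogue.

Scenario families:

* ``A1-A3`` — cryoadhesion analysis: a single freeze of 90/150/210 s followed
  by applicator deactivation, observed through the rewarming window.
* ``B1``   — reference single freeze-thaw cycle: 300 s freeze plus rewarming.
* ``C1-C4`` — two freeze-thaw cycles, 150 s + 150 s freezing with an interim
  thaw of 5/10/15/20 s.
* ``D1-D3`` — two cycles with a 10 s interim thaw starting after 90/150/210 s;
  the second freeze fills the remainder of the 300 s cumulated freezing time.

A terminal thaw is an open-ended observation window; its simulated duration
defaults to 120 s, long enough for the contact patch to cross both phase-change
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

DEFAULT_OBSERVATION_S = 120.0

_CUMULATED_FREEZE_S = 300.0


class CatalogueError(KeyError):
    """Unknown scenario identifier."""


@dataclass(frozen=True)
class Schedule:
    """Ordered freeze/thaw phases of an ablation protocol."""

    name: str
    phases: Tuple[Tuple[str, float], ...]

    @property
    def total_freeze(self) -> float:
        return sum(d for m, d in self.phases if m == "freeze")

    @property
    def n_freezes(self) -> int:
        return sum(1 for m, _ in self.phases if m == "freeze")

    def to_dict(self) -> dict:
        return {"name": self.name,
                "phases": [{"mode": m, "duration": d} for m, d in self.phases]}

    @classmethod
    def from_dict(cls, d: dict) -> "Schedule":
        return cls(name=d["name"],
                   phases=tuple((p["mode"], float(p["duration"])) for p in d["phases"]))


SCENARIO_IDS = ("A1", "A2", "A3", "B1", "C1", "C2", "C3", "C4", "D1", "D2", "D3")

_A_FREEZES = {"A1": 90.0, "A2": 150.0, "A3": 210.0}
_C_THAWS = {"C1": 5.0, "C2": 10.0, "C3": 15.0, "C4": 20.0}
_D_FIRST = {"D1": 90.0, "D2": 150.0, "D3": 210.0}


def make_scenario(scenario_id: str,
                  observation: float = DEFAULT_OBSERVATION_S) -> Schedule:
    """Build the schedule for a catalogued scenario id."""
    sid = scenario_id.upper()
    if sid in _A_FREEZES:
        phases = (("freeze", _A_FREEZES[sid]), ("thaw", observation))
    elif sid == "B1":
        phases = (("freeze", 300.0), ("thaw", observation))
    elif sid in _C_THAWS:
        phases = (("freeze", 150.0), ("thaw", _C_THAWS[sid]),
                  ("freeze", 150.0), ("thaw", observation))
    elif sid in _D_FIRST:
        first = _D_FIRST[sid]
        phases = (("freeze", first), ("thaw", 10.0),
                  ("freeze", _CUMULATED_FREEZE_S - first), ("thaw", observation))
    else:
        raise CatalogueError(f"unknown scenario id {scenario_id!r}")
    return Schedule(name=sid, phases=phases)


def validate(schedule: Schedule) -> List[str]:
    """Check schedule invariants; returns a list of diagnostics (empty = ok)."""
    diags: List[str] = []
    if not schedule.phases:
        diags.append("schedule has no phases")
        return diags
    for i, (mode, duration) in enumerate(schedule.phases):
        if mode not in ("freeze", "thaw"):
            diags.append(f"phase {i}: unknown mode {mode!r}")
        if duration <= 0:
            diags.append(f"phase {i}: duration must be > 0")
    for (m1, _), (m2, _) in zip(schedule.phases[:-1], schedule.phases[1:]):
        if m1 == m2:
            diags.append("modes must alternate")
            break
    if schedule.name and schedule.name[0] in ("C", "D") and \
            abs(schedule.total_freeze - _CUMULATED_FREEZE_S) > 1e-9:
        diags.append(
            f"{schedule.name}: cumulated freezing must be {_CUMULATED_FREEZE_S:.0f} s "
            f"(got {schedule.total_freeze:.0f} s)")
    return diags
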