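"""Eligibility, exclusion and fracture-adjudication rules.

Pure deterministic classifiers encoding the cohort's event definitions:

* A low-trauma (LT) clinical fracture is any confirmed fracture resulting
  from a fall from standing height or less, excluding finger, toe, skull
  and face fractures.
* Major osteoporotic fractures (MOF) are the subset of LT fractures at the
  humerus, forearm, proximal femur or vertebra (so MOF implies LT).
* Subjects with an incident traumatic fracture at a non-excluded site are
  removed from the analysis set; subjects whose only events are at excluded
  sites remain as controls.
* Vertebral deformities require clinical symptoms or radiographic
  confirmation; unconfirmed events are flagged pending and not classified.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

MOF_SITES = frozenset({"humerus", "forearm", "proximal_femur", "vertebra"})
EXCLUDED_SITES = frozenset({"finger", "toe", "skull", "face"})
ALL_SITES = MOF_SITES | EXCLUDED_SITES | frozenset({"rib", "other"})

LOW_TRAUMA = "fall_standing_height_or_less"
HIGH_TRAUMA = "high_trauma"


class EventClass(Enum):
    PENDING = "pending"            # unconfirmed, not classified
    EXCLUDED_SITE = "excluded_site"
    TRAUMATIC = "traumatic"
    LT_ONLY = "lt_fracture"
    LT_MOF = "mof"

    @property
    def is_lt(self) -> bool:
        return self in (EventClass.LT_ONLY, EventClass.LT_MOF)

    @property
    def is_mof(self) -> bool:
        return self is EventClass.LT_MOF


@dataclass(frozen=True)
class FractureEvent:
    site: str
    trauma: str = LOW_TRAUMA
    confirmed: bool = True
    time: float = 0.0

    def __post_init__(self):
        if self.site not in ALL_SITES:
            raise ValueError(f"unknown fracture site {self.site!r}")
        if self.trauma not in (LOW_TRAUMA, HIGH_TRAUMA):
            raise ValueError(f"unknown trauma level {self.trauma!r}")
        if self.time < 0:
            raise ValueError("event time must be non-negative")


@dataclass
class RosterEntry:
    id: str
    has_dxa: bool = True
    followed_up: bool = True
    events: list[FractureEvent] = field(default_factory=list)


def classify_event(event: FractureEvent) -> EventClass:
    """Classify one fracture event; every confirmed event maps to exactly
    one of excluded-site / traumatic / LT-only / LT-and-MOF."""
    if not event.confirmed:
        return EventClass.PENDING
    if event.site in EXCLUDED_SITES:
        return EventClass.EXCLUDED_SITE
    if event.trauma == HIGH_TRAUMA:
        return EventClass.TRAUMATIC
    if event.site in MOF_SITES:
        return EventClass.LT_MOF
    return EventClass.LT_ONLY


def apply_cohort_filters(roster: list[RosterEntry]):
    """Apply the study's eligibility filters in order.

    Removal precedence: missing DXA, then loss of follow-up, then incident
    traumatic fracture (at a non-excluded site); a subject matching several
    reasons is counted once under the first.  Subjects whose only events are
    at excluded sites stay in the analysis set (as potential controls).

    Returns ``(analysis_set, exclusion_counts)``.
    """
    ids = [r.id for r in roster]
    if len(set(ids)) != len(ids):
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate roster ids: {dupes}")
    counts = Counter()
    analysis = []
    for entry in roster:
        if not entry.has_dxa:
            counts["missing_dxa"] += 1
            continue
        if not entry.followed_up:
            counts["lost_followup"] += 1
            continue
        if any(classify_event(ev) is EventClass.TRAUMATIC for ev in entry.events):
            counts["traumatic_fracture"] += 1
            continue
        analysis.append(entry)
    for key in ("missing_dxa", "lost_followup", "traumatic_fracture"):
        counts.setdefault(key, 0)
    return analysis, dict(counts)


def first_event_times(entry: RosterEntry, followup_years: float):
    """Time to first LT fracture and first MOF, censored at follow-up end.

    Returns ``((time_lt, event_lt), (time_mof, event_mof))`` with event
    flags 0/1; pending (unconfirmed) events are ignored.
    """
    lt_times = []
    mof_times = []
    for ev in entry.events:
        cls = classify_event(ev)
        if cls is EventClass.PENDING:
            continue
        if cls.is_lt:
            if ev.time > followup_years:
                raise ValueError(
                    f"event time {ev.time} exceeds follow-up {followup_years} "
                    f"for subject {entry.id}")
            lt_times.append(ev.time)
            if cls.is_mof:
                mof_times.append(ev.time)
    t_lt = (min(lt_times), 1) if lt_times else (followup_years, 0)
    t_mof = (min(mof_times), 1) if mof_times else (followup_years, 0)
    return t_lt, t_mof
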