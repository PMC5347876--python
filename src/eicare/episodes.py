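"""Group a patient's dated events into care episodes.

A *care episode* is a 30.4-day month (anchored at study entry, the first
attendance marker) in which at least one attendance marker occurred.
Clustered repeat measurements within a month collapse into a single episode,
since only the index visit of a cluster would have been scheduled.

Each episode carries the derived clinical state the scheduling rules need:
the lowest CD4 count measured that month (carried forward from the most
recent prior value when none was measured, flagged), the change from the
previous measured CD4, the highest viral load (likewise carried forward),
whether that viral load is a blip (51-200 copies/mL immediately following a
measured value < 50 copies/mL), treatment status, and event flags for ART
start, regimen switch, recency of HIV diagnosis and AIDS diagnosis.

Carried-forward values participate in threshold rules but never generate
CD4 drops or blips: changes are computed only between measured values, so
stale data cannot manufacture phantom deterioration.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date

from .cohort import PatientRecord

#: Length of an algorithm month in days.  30.4 = 152/5 exactly, so month
#: arithmetic is done in integers to avoid float boundary artifacts.
MONTH_DAYS = 30.4


def month_index(date: Date, entry_date: Date) -> int:
    """Index of the 30.4-day month containing ``date``, with the entry date
    mapping to month 0 (i.e. floor(days_since_entry / 30.4))."""
    days = (date - entry_date).days
    if days < 0:
        raise ValueError(f"event date {date} precedes entry date {entry_date}")
    return days * 5 // 152


def month_start_day(m: int) -> int:
    """First integer day offset that falls in month ``m`` (inverse of
    :func:`month_index`): the smallest d with d*5 // 152 == m."""
    return -((-152 * m) // 5)  # ceil(152*m / 5)


@dataclass
class CareEpisode:
    """One attended month with its derived clinical state.

    ``lowest_cd4``/``highest_vl`` may be carried forward from earlier
    measurements (flagged); ``cd4_drop`` is previous measured CD4 minus this
    month's lowest measured CD4 (positive = drop) and is ``None`` unless both
    exist.  ``vl_below_detection`` records whether the highest VL this month
    was an undetectable result stored at its detection bound.
    """

    month_index: int
    episode_date: Date
    lowest_cd4: float | None = None
    cd4_carried: bool = False
    cd4_drop: float | None = None
    highest_vl: float | None = None
    vl_carried: bool = False
    vl_below_detection: bool = False
    vl_is_blip: bool = False
    on_art: bool = False
    started_art_this_episode: bool = False
    started_new_combination_this_episode: bool = False
    within_one_month_of_diagnosis: bool = False
    aids_event_this_episode: bool = False


def _vl_below(value: float, below_detection: bool, bound: float) -> bool:
    """True if a stored viral load is strictly below ``bound`` copies/mL,
    treating an undetectable "<X" result stored as X as below any bound >= X."""
    return value < bound or (below_detection and value <= bound)


def build_episodes(patient: PatientRecord, entry_date: Date | None = None) -> list[CareEpisode]:
    """Derive the ordered care-episode sequence for one patient.

    Months are anchored at ``entry_date`` (default: first attendance
    marker).  Returns one episode per attended month, state derived as
    described in the module docstring.
    """
    if entry_date is None:
        entry_date = patient.entry_date

    by_month: dict[int, list[Date]] = {}
    for d in patient.attendance_dates:
        by_month.setdefault(month_index(d, entry_date), []).append(d)

    cd4s = [m for m in patient.labs if m.kind == "cd4"]
    vls = [m for m in patient.labs if m.kind == "viral_load"]
    art_start = patient.art_start_date()
    switch_dates = [t.date for t in patient.therapy if t.kind == "switch"]

    episodes: list[CareEpisode] = []
    for m in sorted(by_month):
        ep_date = min(by_month[m])
        ep = CareEpisode(month_index=m, episode_date=ep_date)

        # CD4: lowest measured this month, else carry the latest prior value.
        month_cd4 = [x for x in cd4s if month_index(x.date, entry_date) == m]
        prior_cd4 = [x for x in cd4s if month_index(x.date, entry_date) < m]
        if month_cd4:
            ep.lowest_cd4 = min(x.value for x in month_cd4)
            if prior_cd4:
                ep.cd4_drop = prior_cd4[-1].value - ep.lowest_cd4
        elif prior_cd4:
            ep.lowest_cd4 = prior_cd4[-1].value
            ep.cd4_carried = True

        # Viral load: highest measured this month, else carry.
        month_vl = [x for x in vls if month_index(x.date, entry_date) == m]
        prior_vl = [x for x in vls if month_index(x.date, entry_date) < m]
        if month_vl:
            top = max(month_vl, key=lambda x: x.value)
            ep.highest_vl = top.value
            ep.vl_below_detection = top.below_detection
            if prior_vl:
                prev = prior_vl[-1]
                ep.vl_is_blip = (
                    50 < top.value <= 200
                    and not top.below_detection
                    and _vl_below(prev.value, prev.below_detection, 50)
                )
        elif prior_vl:
            ep.highest_vl = prior_vl[-1].value
            ep.vl_below_detection = prior_vl[-1].below_detection
            ep.vl_carried = True

        ep.on_art = art_start is not None and art_start <= ep_date
        ep.started_art_this_episode = (
            art_start is not None
            and art_start >= entry_date
            and month_index(art_start, entry_date) == m
        )
        ep.started_new_combination_this_episode = any(
            d >= entry_date and month_index(d, entry_date) == m for d in switch_dates
        )
        # "within 1 month of diagnosis": at most 30.4 days after diagnosis.
        ep.within_one_month_of_diagnosis = (
            ep_date >= patient.hiv_diagnosis_date
            and (ep_date - patient.hiv_diagnosis_date).days * 5 <= 152
        )
        aids = patient.aids_diagnosis_date
        ep.aids_event_this_episode = (
            aids is not None and aids >= entry_date and month_index(aids, entry_date) == m
        )
        episodes.append(ep)
    return episodes
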