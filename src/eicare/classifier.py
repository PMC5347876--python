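"""The engagement-in-care (EIC) classifier.

Two stages:

1. **Rule engine** (:func:`expected_interval`): map a care episode's
   clinical state to the number of months within which the next care episode
   is expected.  The default rule table encodes out-patient HIV scheduling
   practice — recent HIV diagnosis, AIDS diagnosis, ART start or regimen
   switch all pull the next visit to 2 months; untreated patients are seen
   every 2-6 months depending mainly on CD4 count; treated patients every
   2-6 months depending mainly on viral load, with 6 months the routine
   maximum and 2 months the shortest interval (a visit may fall anywhere in
   its month, so nothing shorter is expected).  When several conditions hold
   at once, the *minimum* of their intervals applies; the untreated and
   on-ART blocks are not mutually exclusive gates (the episode in which ART
   starts can fire rows from both).

2. **Month classifier** (:func:`classify_months`): given the episode
   sequence and each episode's expected interval N, label every follow-up
   month from 1 onward.  After an episode at month m, months m+1 .. m+N are
   in care; if the next episode only occurs at month m' > m+N, months
   m+N+1 .. m' are out of care — including the re-attendance month itself
   when it falls beyond the window.  Follow-up is censored by default at the
   last episode, so the measure captures intermittent disengagement rather
   than terminal loss to follow-up; passing a later ``follow_up_end_month``
   (e.g. from an administrative end date) extends the final window.

Every threshold and interval lives in :class:`RuleConfig`, so the table can
be adapted to changed monitoring guidelines or local clinic policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .cohort import MonthClassification
from .episodes import CareEpisode

FALLBACK = "fallback"


@dataclass
class RuleConfig:
    """Thresholds and intervals of the scheduling rule table.

    Units: CD4 in cells/uL, viral load in copies/mL, intervals in 30.4-day
    months.  Defaults encode the standard table; all values are editable and
    serializable to/from YAML.
    """

    # event-driven rows
    interval_diagnosis: int = 2       # within 1 month of HIV diagnosis
    interval_aids: int = 2            # AIDS diagnosis this episode month
    interval_art_start: int = 2
    interval_art_switch: int = 2      # started new combination

    # untreated block
    cd4_low: float = 350.0            # "<= 350" boundary
    cd4_high: float = 500.0           # ">= 500" boundary
    cd4_drop_threshold: float = 100.0
    vl_high: float = 100_000.0
    interval_untreated_low_cd4_drop: int = 2
    interval_untreated_low_cd4_stable: int = 4
    interval_untreated_mid_cd4: int = 4
    interval_untreated_high_cd4_drop: int = 4
    interval_untreated_high_cd4_viraemic: int = 4
    interval_untreated_routine: int = 6

    # on-ART block
    vl_suppressed: float = 50.0       # "<= 50" boundary
    vl_lowlevel_max: float = 200.0
    cd4_treated: float = 200.0
    interval_treated_viraemic: int = 2
    interval_treated_lowlevel: int = 2
    interval_treated_blip: int = 4
    interval_treated_suppressed_low_cd4: int = 4
    interval_treated_routine: int = 6

    # applied when no row is satisfiable (e.g. no labs ever recorded)
    interval_fallback: int = 4

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("interval_") and (int(v) != v or v < 1):
                raise ValueError(f"{f.name} must be a positive integer, got {v!r}")
            if not f.name.startswith("interval_") and v <= 0:
                raise ValueError(f"{f.name} must be positive, got {v!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown rule-config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)


@dataclass(frozen=True)
class ExpectedInterval:
    """Months until the next expected care episode, with the identifiers of
    every rule-table row the episode satisfied (months = their minimum)."""

    months: int
    fired_conditions: tuple[str, ...]


def expected_interval(episode: CareEpisode, config: RuleConfig | None = None) -> ExpectedInterval:
    """Evaluate the rule table on one episode and return the minimum
    interval over all satisfied rows.

    Missing values make the rows that depend on them unsatisfiable; when no
    row at all fires, the fallback interval applies with the single
    condition identifier ``"fallback"``.
    """
    cfg = config or RuleConfig()
    fired: list[tuple[str, int]] = []

    if episode.within_one_month_of_diagnosis:
        fired.append(("within_1m_of_diagnosis", cfg.interval_diagnosis))
    if episode.aids_event_this_episode:
        fired.append(("aids_diagnosis", cfg.interval_aids))
    if episode.started_art_this_episode:
        fired.append(("started_art", cfg.interval_art_start))
    if episode.started_new_combination_this_episode:
        fired.append(("started_new_combination", cfg.interval_art_switch))

    cd4 = episode.lowest_cd4
    vl = episode.highest_vl
    drop = episode.cd4_drop  # None when fewer than two measured values exist
    any_drop = drop is not None and drop > 0
    big_drop = drop is not None and drop >= cfg.cd4_drop_threshold

    if not episode.on_art and cd4 is not None:
        if cd4 <= cfg.cd4_low:
            if any_drop:
                fired.append(("untreated_cd4_low_drop", cfg.interval_untreated_low_cd4_drop))
            else:
                fired.append(("untreated_cd4_low_stable", cfg.interval_untreated_low_cd4_stable))
        elif cd4 < cfg.cd4_high:
            fired.append(("untreated_cd4_mid", cfg.interval_untreated_mid_cd4))
        else:  # cd4 >= cfg.cd4_high
            if big_drop:
                fired.append(("untreated_cd4_high_drop", cfg.interval_untreated_high_cd4_drop))
            elif vl is not None and vl >= cfg.vl_high:
                fired.append(
                    ("untreated_cd4_high_viraemic", cfg.interval_untreated_high_cd4_viraemic)
                )
            elif vl is not None:
                fired.append(("untreated_routine", cfg.interval_untreated_routine))

    if episode.on_art and vl is not None:
        if vl > cfg.vl_lowlevel_max:
            fired.append(("treated_vl_high", cfg.interval_treated_viraemic))
        elif vl > cfg.vl_suppressed:
            if episode.vl_is_blip:
                fired.append(("treated_vl_blip", cfg.interval_treated_blip))
            else:
                fired.append(("treated_vl_lowlevel", cfg.interval_treated_lowlevel))
        elif cd4 is not None:
            if cd4 <= cfg.cd4_treated:
                fired.append(
                    ("treated_suppressed_low_cd4", cfg.interval_treated_suppressed_low_cd4)
                )
            else:
                fired.append(("treated_routine", cfg.interval_treated_routine))

    if not fired:
        return ExpectedInterval(cfg.interval_fallback, (FALLBACK,))
    months = min(iv for _, iv in fired)
    return ExpectedInterval(months, tuple(name for name, _ in fired))


#: All condition identifiers the rule engine can emit (excluding fallback).
CONDITION_IDS = (
    "within_1m_of_diagnosis",
    "aids_diagnosis",
    "started_art",
    "started_new_combination",
    "untreated_cd4_low_drop",
    "untreated_cd4_low_stable",
    "untreated_cd4_mid",
    "untreated_cd4_high_drop",
    "untreated_cd4_high_viraemic",
    "untreated_routine",
    "treated_vl_high",
    "treated_vl_lowlevel",
    "treated_vl_blip",
    "treated_suppressed_low_cd4",
    "treated_routine",
)


def classify_months(
    episodes: list[CareEpisode],
    follow_up_end_month: int | None = None,
    config: RuleConfig | None = None,
    patient_id: str = "",
) -> list[MonthClassification]:
    """Label every follow-up month 1..``follow_up_end_month`` in/out of care.

    ``follow_up_end_month`` defaults to the last episode's month (censoring
    at the last recorded attendance).  Months are labelled against the
    expectation window of the most recent preceding episode; each month
    appears exactly once.
    """
    if not episodes:
        raise ValueError("no care episodes to classify")
    months = [ep.month_index for ep in episodes]
    if months != sorted(months) or len(set(months)) != len(months):
        raise ValueError("episodes must be ordered with strictly increasing month_index")
    last = months[-1]
    if follow_up_end_month is None:
        follow_up_end_month = last
    if follow_up_end_month < last:
        raise ValueError(
            f"follow_up_end_month {follow_up_end_month} precedes last episode month {last}"
        )

    cfg = config or RuleConfig()
    out: list[MonthClassification] = []
    for i, ep in enumerate(episodes):
        n = expected_interval(ep, cfg).months
        m = ep.month_index
        nxt = episodes[i + 1].month_index if i + 1 < len(episodes) else follow_up_end_month
        in_until = min(m + n, nxt)
        for month in range(m + 1, in_until + 1):
            out.append(MonthClassification(patient_id, month, "in_care", m))
        for month in range(m + n + 1, nxt + 1):
            out.append(MonthClassification(patient_id, month, "out_of_care", m))
    return out


def patient_eic(classifications: list[MonthClassification]) -> float:
    """Fraction of follow-up months in care (the per-patient EIC measure)."""
    if not classifications:
        raise ValueError("cannot compute EIC of an empty classification list")
    n_in = sum(1 for c in classifications if c.label == "in_care")
    return n_in / len(classifications)
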