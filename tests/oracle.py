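"""Independent brute-force oracle for the month classifier, plus random
episode-state generators.

The walker labels months one at a time, maintaining only "which episode is
the current anchor and how long is its expectation window" — a deliberately
different formulation from the production classifier's window arithmetic.
"""

from __future__ import annotations

import random
from datetime import date as Date, timedelta

from eicare.episodes import CareEpisode, month_start_day

_BASE = Date(2005, 1, 1)


def walk_labels(
    episode_months: list[int], intervals: list[int], end: int
) -> tuple[dict[int, str], dict[int, int]]:
    """Label months 1..end by walking them one at a time.

    A month's anchor is the most recent episode strictly before it; the
    month is in care iff it falls within that episode's expectation window.
    Returns (labels, anchors) keyed by month.
    """
    labels: dict[int, str] = {}
    anchors: dict[int, int] = {}
    j = 0
    for month in range(1, end + 1):
        while j + 1 < len(episode_months) and episode_months[j + 1] < month:
            j += 1
        m, n = episode_months[j], intervals[j]
        labels[month] = "in_care" if month <= m + n else "out_of_care"
        anchors[month] = m
    return labels, anchors


def random_episode_state(rng: random.Random, month: int = 0) -> CareEpisode:
    """A random but internally consistent episode clinical state."""
    ep = CareEpisode(
        month_index=month,
        episode_date=_BASE + timedelta(days=month_start_day(month)),
    )
    ep.on_art = rng.random() < 0.5
    ep.within_one_month_of_diagnosis = rng.random() < 0.08
    ep.aids_event_this_episode = rng.random() < 0.05
    ep.started_art_this_episode = ep.on_art and rng.random() < 0.1
    ep.started_new_combination_this_episode = ep.on_art and rng.random() < 0.05

    if rng.random() < 0.85:
        ep.lowest_cd4 = float(rng.randint(10, 900))
        if rng.random() < 0.6:
            ep.cd4_drop = float(rng.randint(-150, 250))
        else:
            ep.cd4_carried = rng.random() < 0.3
    if rng.random() < 0.85:
        bucket = rng.random()
        if bucket < 0.3:
            ep.highest_vl, ep.vl_below_detection = 50.0, True
        elif bucket < 0.55:
            ep.highest_vl = float(rng.randint(51, 200))
        elif bucket < 0.85:
            ep.highest_vl = float(rng.randint(201, 100_000))
        else:
            ep.highest_vl = float(rng.randint(100_000, 1_000_000))
        if (
            ep.highest_vl is not None
            and 50 < ep.highest_vl <= 200
            and not ep.vl_below_detection
        ):
            ep.vl_is_blip = rng.random() < 0.5
        ep.vl_carried = rng.random() < 0.2
    return ep


def random_episode_sequence(rng: random.Random) -> tuple[list[CareEpisode], int]:
    """A random ordered episode sequence starting at month 0, plus a
    follow-up end month at or beyond the last episode."""
    n = rng.randint(2, 6)
    months = [0]
    for _ in range(n - 1):
        months.append(months[-1] + rng.randint(1, 10))
    episodes = [random_episode_state(rng, m) for m in months]
    episodes[0].within_one_month_of_diagnosis = rng.random() < 0.7
    end = months[-1] + rng.choice([0, 0, 0, rng.randint(1, 8)])
    return episodes, end
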