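"""One minimal episode state per scheduling rule-table row.

Each case is (row_id, episode_kwargs, expected_months) where the state
satisfies exactly that row, so both the interval and the fired-condition
identifier can be asserted.
"""

ROW_CASES = [
    ("within_1m_of_diagnosis", dict(within_one_month_of_diagnosis=True), 2),
    ("aids_diagnosis", dict(aids_event_this_episode=True), 2),
    ("started_art", dict(started_art_this_episode=True), 2),
    ("started_new_combination", dict(started_new_combination_this_episode=True), 2),
    # untreated block
    ("untreated_cd4_low_drop", dict(lowest_cd4=340.0, cd4_drop=10.0), 2),
    ("untreated_cd4_low_stable", dict(lowest_cd4=340.0), 4),
    ("untreated_cd4_mid", dict(lowest_cd4=420.0), 4),
    ("untreated_cd4_high_drop", dict(lowest_cd4=510.0, cd4_drop=120.0), 4),
    (
        "untreated_cd4_high_viraemic",
        dict(lowest_cd4=510.0, cd4_drop=20.0, highest_vl=150_000.0),
        4,
    ),
    ("untreated_routine", dict(lowest_cd4=510.0, highest_vl=30_000.0), 6),
    # on-ART block
    ("treated_vl_high", dict(on_art=True, highest_vl=500.0), 2),
    ("treated_vl_lowlevel", dict(on_art=True, highest_vl=120.0, vl_is_blip=False), 2),
    ("treated_vl_blip", dict(on_art=True, highest_vl=120.0, vl_is_blip=True), 4),
    (
        "treated_suppressed_low_cd4",
        dict(on_art=True, highest_vl=50.0, vl_below_detection=True, lowest_cd4=180.0),
        4,
    ),
    ("treated_routine", dict(on_art=True, highest_vl=40.0, lowest_cd4=420.0), 6),
]
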