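"""Rule engine and month classifier."""

import random
from datetime import date as Date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eicare.classifier import (
    FALLBACK,
    RuleConfig,
    classify_months,
    expected_interval,
    patient_eic,
)
from eicare.episodes import CareEpisode, build_episodes
from eicare.worked_example import worked_example_patient
from oracle import random_episode_state, walk_labels
from rule_cases import ROW_CASES


def _episode(month=0, **kwargs) -> CareEpisode:
    return CareEpisode(month_index=month, episode_date=Date(2005, 1, 1), **kwargs)


@pytest.mark.parametrize("row_id,state,months", ROW_CASES, ids=[c[0] for c in ROW_CASES])
def test_each_rule_row_fires_alone_with_its_printed_interval(row_id, state, months):
    result = expected_interval(_episode(**state))
    assert result.fired_conditions == (row_id,)
    assert result.months == months


def test_minimum_rule_when_multiple_conditions_apply():
    # ART started in an episode whose labs alone would imply 6 months
    result = expected_interval(
        _episode(started_art_this_episode=True, on_art=True,
                 highest_vl=40.0, lowest_cd4=420.0)
    )
    assert result.months == 2
    assert set(result.fired_conditions) == {"started_art", "treated_routine"}


def test_fallback_applies_when_no_row_is_satisfiable():
    result = expected_interval(_episode())
    assert result.months == 4
    assert result.fired_conditions == (FALLBACK,)
    # on ART, suppressed VL but no CD4 ever: no row covers this state either
    result = expected_interval(
        _episode(on_art=True, highest_vl=50.0, vl_below_detection=True)
    )
    assert result.fired_conditions == (FALLBACK,)


def test_below_detection_viral_load_satisfies_suppressed_threshold():
    result = expected_interval(
        _episode(on_art=True, highest_vl=50.0, vl_below_detection=True, lowest_cd4=420.0)
    )
    assert result.months == 6


def test_rule_config_is_editable_and_validated(tmp_path):
    cfg = RuleConfig(interval_treated_routine=12)
    assert expected_interval(
        _episode(on_art=True, highest_vl=40.0, lowest_cd4=420.0), cfg
    ).months == 12
    path = tmp_path / "rules.yaml"
    cfg.to_yaml(path)
    assert RuleConfig.from_yaml(path) == cfg
    with pytest.raises(ValueError, match="positive"):
        RuleConfig(interval_untreated_routine=0)
    (tmp_path / "bad.yaml").write_text("no_such_key: 3\n")
    with pytest.raises(ValueError, match="no_such_key"):
        RuleConfig.from_yaml(tmp_path / "bad.yaml")


def test_adding_a_condition_never_increases_the_interval():
    rng = random.Random(20240)
    for _ in range(500):
        ep = random_episode_state(rng)
        base = expected_interval(ep).months
        ep.started_new_combination_this_episode = True
        assert expected_interval(ep).months <= base


@given(st.integers(min_value=0, max_value=2**32 - 1))
@settings(derandomize=True, max_examples=300)
def test_interval_always_in_2_4_6_under_default_config(seed):
    ep = random_episode_state(random.Random(seed))
    assert expected_interval(ep).months in (2, 4, 6)


# ---------------------------------------------------------------------------
# month classification


def test_worked_example_months_and_eic():
    episodes = build_episodes(worked_example_patient())
    cls = classify_months(episodes, follow_up_end_month=18)
    out = sorted(c.month_index for c in cls if c.label == "out_of_care")
    assert out == [3, 4, 9, 12]
    assert len(cls) == 18
    assert patient_eic(cls) == pytest.approx(14 / 18)


def test_gap_within_interval_yields_no_out_of_care_months():
    eps = [_episode(0, within_one_month_of_diagnosis=True), _episode(2, lowest_cd4=400.0)]
    cls = classify_months(eps)
    assert [(c.month_index, c.label) for c in cls] == [(1, "in_care"), (2, "in_care")]


def test_long_gap_splits_at_expectation_window():
    # episodes at months 0 and 10 with a 6-month window: 1-6 in, 7-10 out
    eps = [_episode(0, on_art=True, highest_vl=40.0, lowest_cd4=420.0),
           _episode(10, lowest_cd4=400.0)]
    cls = classify_months(eps)
    labels = {c.month_index: c.label for c in cls}
    assert all(labels[m] == "in_care" for m in range(1, 7))
    assert all(labels[m] == "out_of_care" for m in range(7, 11))
    assert all(c.anchor_episode_month == 0 for c in cls)


def test_default_censoring_at_last_episode_and_explicit_extension():
    eps = [_episode(0, within_one_month_of_diagnosis=True), _episode(3, lowest_cd4=400.0)]
    assert max(c.month_index for c in classify_months(eps)) == 3
    extended = classify_months(eps, follow_up_end_month=10)
    labels = {c.month_index: c.label for c in extended}
    assert len(extended) == 10
    # the final episode (CD4 400, untreated -> 4 months) covers months 4-7
    assert all(labels[m] == "in_care" for m in range(4, 8))
    assert all(labels[m] == "out_of_care" for m in (8, 9, 10))


def test_classification_input_validation():
    with pytest.raises(ValueError, match="no care episodes"):
        classify_months([])
    eps = [_episode(4), _episode(0)]
    with pytest.raises(ValueError, match="strictly increasing"):
        classify_months(eps)
    with pytest.raises(ValueError, match="precedes last episode"):
        classify_months([_episode(0), _episode(5)], follow_up_end_month=3)


def test_patient_eic_counts_fraction_in_care():
    eps = [_episode(0, within_one_month_of_diagnosis=True), _episode(2)]
    assert patient_eic(classify_months(eps)) == 1.0
    with pytest.raises(ValueError, match="empty"):
        patient_eic([])


@given(st.integers(min_value=0, max_value=2**32 - 1))
@settings(derandomize=True, max_examples=300)
def test_partition_every_month_labelled_exactly_once(seed):
    from oracle import random_episode_sequence

    episodes, end = random_episode_sequence(random.Random(seed))
    cls = classify_months(episodes, follow_up_end_month=end)
    assert sorted(c.month_index for c in cls) == list(range(1, end + 1))


def test_perfect_attendance_implies_full_engagement():
    # every gap equals the expected interval exactly
    rng = random.Random(77)
    for _ in range(200):
        episodes = [random_episode_state(rng, 0)]
        for _ in range(4):
            n = expected_interval(episodes[-1]).months
            episodes.append(random_episode_state(rng, episodes[-1].month_index + n))
        cls = classify_months(episodes)
        assert patient_eic(cls) == 1.0


def test_classifier_agrees_with_month_walking_oracle_on_random_sequences():
    from oracle import random_episode_sequence

    rng = random.Random(991)
    for _ in range(2000):
        episodes, end = random_episode_sequence(rng)
        intervals = [expected_interval(ep).months for ep in episodes]
        cls = classify_months(episodes, follow_up_end_month=end)
        want_labels, want_anchors = walk_labels(
            [ep.month_index for ep in episodes], intervals, end
        )
        assert {c.month_index: c.label for c in cls} == want_labels
        assert {c.month_index: c.anchor_episode_month for c in cls} == want_anchors
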