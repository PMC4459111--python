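"""Episode merging: the three date-window conditions and the claim scan."""

import datetime as dt
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amiepisodes.episode_builder import (
    MergeRule,
    attribute_episode,
    build_episodes,
    compute_los,
    merge_condition,
    oracle_build_episodes,
    read_episodes,
    write_episodes,
)

from conftest import make_claim


def partition_of(episodes):
    return {frozenset(e.member_claim_ids) for e in episodes}


class TestLengthOfStay:
    @pytest.mark.parametrize(
        "admission, discharge, los",
        [
            ("2007-01-01", "2007-01-01", 0),  # same-day discharge
            ("2007-01-01", "2007-01-04", 3),
            ("2008-02-28", "2008-03-01", 2),  # leap-year February
        ],
    )
    def test_calendar_day_difference(self, admission, discharge, los):
        claim = make_claim(admission=admission, discharge=discharge)
        assert compute_los(claim) == los

    def test_both_ends_convention_adds_one(self):
        claim = make_claim(admission="2007-01-01", discharge="2007-01-04")
        assert compute_los(claim, MergeRule(los_counts_both_ends=True)) == 4


class TestMergeCondition:
    @pytest.mark.parametrize(
        "first_dates, second_dates, merged, conditions",
        [
            # admission gap 24 <= 28
            (("2007-03-01", "2007-03-10"), ("2007-03-25", "2007-04-02"), True, {"C1"}),
            # admission gap 31 > 28 but only 2 days past the first discharge
            (("2007-03-01", "2007-03-30"), ("2007-04-01", "2007-04-20"), True, {"C2"}),
            # far apart, but the second stay is under 3 days
            (("2007-01-01", "2007-01-05"), ("2007-06-01", "2007-06-02"), True, {"C3"}),
            # no condition fires
            (("2007-03-01", "2007-03-05"), ("2007-04-15", "2007-04-25"), False, set()),
            # inclusive boundaries: exactly 28 days between admissions
            (("2007-03-01", "2007-03-02"), ("2007-03-29", "2007-04-10"), True, {"C1"}),
            # 29 days between admissions, 27 past discharge, stay of 12
            (("2007-03-01", "2007-03-02"), ("2007-03-30", "2007-04-11"), False, set()),
            # exactly 3 days past the first discharge
            (("2007-03-01", "2007-03-30"), ("2007-04-02", "2007-04-20"), True, {"C2"}),
            # overlapping claims (transfer): negative gap fires C2
            (("2007-03-01", "2007-03-10"), ("2007-03-05", "2007-03-20"), True, {"C1", "C2"}),
            # stay of exactly 3 days does NOT fire C3 (strict <)
            (("2007-01-01", "2007-01-05"), ("2007-06-01", "2007-06-04"), False, set()),
        ],
    )
    def test_three_conditions(self, first_dates, second_dates, merged, conditions):
        first = make_claim("C1", admission=first_dates[0], discharge=first_dates[1])
        second = make_claim("C2", admission=second_dates[0], discharge=second_dates[1])
        decision = merge_condition(first, second)
        assert decision.merge is merged
        assert set(decision.conditions_met) == conditions

    def test_cross_patient_comparison_is_an_error(self):
        with pytest.raises(ValueError, match="patient"):
            merge_condition(make_claim("C1"), make_claim("C2", patient_id="P2"))

    def test_unsorted_pair_is_an_error(self):
        first = make_claim("C1", admission="2007-03-10", discharge="2007-03-12")
        second = make_claim("C2", admission="2007-03-01", discharge="2007-03-02")
        with pytest.raises(ValueError, match="order"):
            merge_condition(first, second)

    def test_thresholds_must_be_non_negative_integers(self):
        with pytest.raises(ValueError):
            MergeRule(admission_window_days=-1)
        with pytest.raises(ValueError):
            MergeRule(anchor="middle")


class TestBuildEpisodes:
    def test_chained_merge_then_break(self):
        # claim 2 merges via C2 (1 day past discharge); claim 3 fails all three
        claims = [
            make_claim("C1", admission="2007-01-01", discharge="2007-01-31"),
            make_claim("C2", admission="2007-02-01", discharge="2007-02-20"),
            make_claim("C3", admission="2007-03-25", discharge="2007-03-28"),
        ]
        episodes = build_episodes(claims)
        assert [e.n_claims for e in episodes] == [2, 1]
        assert episodes[0].member_claim_ids == ("C1", "C2")
        assert episodes[0].index_admission_date == dt.date(2007, 1, 1)
        assert episodes[0].final_discharge_date == dt.date(2007, 2, 20)

    def test_pairwise_non_mergeable_claims_stay_separate(self):
        claims = [
            make_claim(f"C{i}", admission=f"2007-{2 * i + 1:02d}-01",
                       discharge=f"2007-{2 * i + 1:02d}-10")
            for i in range(4)
        ]
        assert len(build_episodes(claims)) == 4

    def test_patients_never_merge_even_with_identical_dates(self):
        claims = [
            make_claim("C1", patient_id="P1"),
            make_claim("C2", patient_id="P2"),
        ]
        episodes = build_episodes(claims)
        assert len(episodes) == 2
        assert {e.patient_id for e in episodes} == {"P1", "P2"}

    def test_output_invariant_to_input_order(self):
        rng = random.Random(7)
        claims = [
            make_claim(f"C{i}", patient_id=f"P{i % 3}",
                       admission=(dt.date(2007, 1, 1) + dt.timedelta(days=13 * i)).isoformat(),
                       discharge=(dt.date(2007, 1, 1) + dt.timedelta(days=13 * i + 2)).isoformat())
            for i in range(12)
        ]
        baseline = build_episodes(claims)
        for _ in range(5):
            rng.shuffle(claims)
            assert build_episodes(claims) == baseline

    def test_conservation_no_claim_lost_or_duplicated(self):
        claims = [
            make_claim(f"C{i}", patient_id=f"P{i % 4}",
                       admission=(dt.date(2007, 1, 1) + dt.timedelta(days=11 * i)).isoformat(),
                       discharge=(dt.date(2007, 1, 1) + dt.timedelta(days=11 * i + 5)).isoformat())
            for i in range(20)
        ]
        episodes = build_episodes(claims)
        member_ids = [cid for e in episodes for cid in e.member_claim_ids]
        assert sorted(member_ids) == sorted(c.claim_id for c in claims)

    def test_index_anchor_reanchors_condition_one(self):
        # three claims each 20 days apart: rolling anchor chains all three,
        # index anchor breaks at claim 3 (40 days from the episode index)
        claims = [
            make_claim("C1", admission="2007-01-01", discharge="2007-01-05"),
            make_claim("C2", admission="2007-01-21", discharge="2007-01-28"),
            make_claim("C3", admission="2007-02-10", discharge="2007-02-17"),
        ]
        assert len(build_episodes(claims, MergeRule(anchor="rolling"))) == 1
        assert len(build_episodes(claims, MergeRule(anchor="index"))) == 2

    def test_monotone_in_admission_window(self):
        rng = random.Random(42)
        claims = []
        for p in range(30):
            day = dt.date(2007, 1, 1)
            for i in range(rng.randint(1, 6)):
                los = rng.randint(0, 20)
                claims.append(
                    make_claim(f"P{p}C{i}", patient_id=f"P{p}",
                               admission=day.isoformat(),
                               discharge=(day + dt.timedelta(days=los)).isoformat())
                )
                day += dt.timedelta(days=los + rng.randint(1, 60))
        counts = [
            len(build_episodes(claims, MergeRule(admission_window_days=w)))
            for w in (0, 7, 14, 28, 56)
        ]
        assert counts == sorted(counts, reverse=True)
        assert 1 <= counts[-1] <= len(claims)


class TestAttribution:
    def test_single_emergency_claim(self):
        episode = attribute_episode([make_claim(admission_route="emergency")])
        assert episode.ed_admission and not episode.has_invasive
        assert episode.year == 2007
        assert episode.n_claims == 1

    def test_ed_policy_index_versus_any(self):
        claims = [
            make_claim("C1", admission_route="other",
                       admission="2007-01-01", discharge="2007-01-10"),
            make_claim("C2", admission_route="emergency",
                       admission="2007-01-11", discharge="2007-01-20"),
        ]
        assert attribute_episode(claims, ed_policy="index").ed_admission is False
        assert attribute_episode(claims, ed_policy="any").ed_admission is True

    def test_invasive_from_any_member_claim(self):
        claims = [
            make_claim("C1", admission="2007-01-01", discharge="2007-01-10"),
            make_claim("C2", admission="2007-01-11", discharge="2007-01-20",
                       proc_codes=("PCI01",)),
        ]
        assert attribute_episode(claims).has_invasive is True

    def test_empty_member_list_is_an_error(self):
        with pytest.raises(ValueError):
            attribute_episode([])

    def test_year_from_index_claim_across_year_boundary(self):
        claims = [
            make_claim("C1", admission="2007-12-20", discharge="2007-12-31"),
            make_claim("C2", admission="2008-01-01", discharge="2008-01-10"),
        ]
        (episode,) = build_episodes(claims)
        assert episode.year == 2007


claim_strategy = st.tuples(
    st.integers(min_value=0, max_value=70),  # admission offset (days)
    st.integers(min_value=0, max_value=12),  # length of stay
)


class TestOracleEquivalence:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(claim_strategy, min_size=1, max_size=6))
    def test_scan_equals_union_find_oracle(self, spans):
        base = dt.date(2007, 1, 1)
        claims = [
            make_claim(f"C{i}", admission=(base + dt.timedelta(days=off)).isoformat(),
                       discharge=(base + dt.timedelta(days=off + los)).isoformat())
            for i, (off, los) in enumerate(spans)
        ]
        assert build_episodes(claims) == oracle_build_episodes(claims)

    def test_single_claim_patients_trivially_agree(self):
        claims = [make_claim(f"C{i}", patient_id=f"P{i}") for i in range(5)]
        assert build_episodes(claims) == oracle_build_episodes(claims)


class TestEpisodesCsv:
    def test_round_trip(self, tmp_path):
        claims = [
            make_claim("C1", admission="2007-01-01", discharge="2007-01-31",
                       proc_codes=("CAG01",)),
            make_claim("C2", admission="2007-02-01", discharge="2007-02-03"),
            make_claim("C3", patient_id="P2", sex="female", admission_route="other"),
        ]
        episodes = build_episodes(claims)
        path = tmp_path / "episodes.csv"
        write_episodes(episodes, path)
        assert read_episodes(path) == episodes
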