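"""Line provenance: introducers, sources, novelty and trends."""

import pytest

from codeculture.provenance import (
    build_provenance_index,
    recent_sources,
    recombination_trend,
    source_profile,
    source_profiles,
)


def brute_force_sources(contest, i):
    """Quadratic oracle scanning all prior entries for each line of entry i."""
    entry = contest.entries[i]
    original, recent, novel_occ = set(), set(), 0
    for line, count in entry.lines.items():
        earlier = [k for k in range(i) if line in contest.entries[k].lines]
        all_carriers = [k for k in range(len(contest.entries)) if line in contest.entries[k].lines]
        if min(all_carriers) == i:
            novel_occ += count
        else:
            original.add(min(all_carriers))
            recent.add(max(earlier))
    return original, recent, novel_occ


class TestProvenanceIndex:
    def test_first_introducers(self, make_contest):
        contest = make_contest(
            [
                ("e1", ["a", "b"], 3.0),
                ("e2", ["c"], 2.0),
                ("e3", ["a", "c", "d"], 1.0),
            ]
        )
        index = build_provenance_index(contest)
        assert {l: i for l, i in index.first_introducer.items()} == {
            "a": 0, "b": 0, "c": 1, "d": 2,
        }
        assert index.carriers["a"] == [0, 2]

    def test_single_entry_contest(self, make_contest):
        contest = make_contest([("e1", ["a", "b"], 1.0)])
        index = build_provenance_index(contest)
        assert all(i == 0 for i in index.first_introducer.values())

    def test_line_in_all_entries(self, make_contest):
        contest = make_contest([("e1", ["a"], 1.0), ("e2", ["a"], 2.0), ("e3", ["a"], 3.0)])
        index = build_provenance_index(contest)
        assert index.carriers["a"] == [0, 1, 2]


class TestSourceProfiles:
    def test_hand_example(self, make_contest):
        contest = make_contest(
            [
                ("e1", ["a", "b"], 3.0, "ann"),
                ("e2", ["c"], 2.0, "bob"),
                ("e3", ["a", "c", "d"], 1.0, "cho"),
            ]
        )
        index = build_provenance_index(contest)
        p = source_profile(contest, 2, index)
        assert p.n_original_sources == 2
        assert p.n_novel_lines == 1
        assert p.n_source_authors == 2
        assert p.novel_fraction == pytest.approx(1 / 3)

    def test_first_entry_fully_novel(self, make_contest):
        contest = make_contest([("e1", {"a": 2, "b": 1}, 1.0), ("e2", ["c"], 2.0)])
        p = source_profile(contest, 0, build_provenance_index(contest))
        assert p.n_original_sources == 0 and p.novel_fraction == 1.0

    def test_pure_copy_has_one_source_no_novelty(self, make_contest):
        contest = make_contest([("e1", ["a", "b"], 1.0), ("e2", ["a", "b"], 2.0)])
        p = source_profile(contest, 1, build_provenance_index(contest))
        assert p.n_original_sources == 1 and p.novel_fraction == 0.0

    def test_recent_sources_single_latest_carrier(self, make_contest):
        contest = make_contest(
            [("e1", ["a"], 1.0), ("e2", ["a", "b"], 2.0), ("e3", ["a", "b"], 3.0)]
        )
        index = build_provenance_index(contest)
        assert recent_sources(contest, 2, index) == 1  # e2 carries both most recently

    def test_recent_sources_two_carriers(self, make_contest):
        contest = make_contest(
            [("e1", ["a"], 1.0), ("e2", ["b"], 2.0), ("e3", ["a", "b"], 3.0)]
        )
        index = build_provenance_index(contest)
        assert recent_sources(contest, 2, index) == 2

    def test_only_novel_lines_zero_recent(self, make_contest):
        contest = make_contest([("e1", ["a"], 1.0), ("e2", ["z"], 2.0)])
        index = build_provenance_index(contest)
        assert recent_sources(contest, 1, index) == 0

    def test_exclude_same_author_sources(self, make_contest):
        contest = make_contest(
            [("e1", ["a"], 1.0, "ann"), ("e2", ["a", "b"], 2.0, "ann")]
        )
        index = build_provenance_index(contest)
        with_self = source_profile(contest, 1, index)
        without = source_profile(contest, 1, index, exclude_same_author=True)
        assert with_self.n_original_sources == 1
        assert without.n_original_sources == 0

    def test_matches_quadratic_brute_force_on_synthetic(self):
        from codeculture.synthetic import SimulationConfig, simulate_contest

        contest, _ = simulate_contest(SimulationConfig(seed=11, n_entries=40, n_agents=8))
        index = build_provenance_index(contest)
        for i in range(len(contest.entries)):
            p = source_profile(contest, i, index)
            original, recent, novel_occ = brute_force_sources(contest, i)
            assert p.n_original_sources == len(original)
            assert p.n_recent_sources == len(recent)
            assert p.n_novel_lines == novel_occ

    def test_novel_distinct_conservation(self):
        from codeculture.synthetic import SimulationConfig, simulate_contest

        contest, _ = simulate_contest(SimulationConfig(seed=4, n_entries=60, n_agents=10))
        profiles = source_profiles(contest)
        all_lines = set()
        for e in contest.entries:
            all_lines.update(e.lines)
        assert sum(p.n_novel_distinct for p in profiles) == len(all_lines)

    def test_monotone_accumulation_in_copy_chain(self, make_contest):
        # each entry copies everything so far and adds one novel line:
        # original sources of entry i = i (all its ancestors)
        rows = []
        lines: list[str] = []
        for i in range(8):
            lines = lines + [f"l{i}"]
            rows.append((f"e{i}", list(lines), float(10 - i)))
        contest = make_contest(rows)
        profiles = source_profiles(contest)
        assert [p.n_original_sources for p in profiles] == list(range(8))
        assert all(p.n_novel_distinct == 1 for p in profiles)


class TestRecombinationTrend:
    def test_copy_heavy_contest_positive_trend(self):
        from codeculture.synthetic import SimulationConfig, simulate_contest

        positives = 0
        for seed in range(20):
            contest, _ = simulate_contest(
                SimulationConfig(seed=seed, n_entries=150, n_agents=20)
            )
            trend = recombination_trend(contest.daylight_view())
            if trend["trend_original_vs_time"].rho > 0:
                positives += 1
        assert positives >= 18

    def test_fully_novel_contest_flagged(self, make_contest):
        contest = make_contest([("e1", ["a"], 1.0), ("e2", ["b"], 2.0), ("e3", ["c"], 3.0)])
        trend = recombination_trend(contest)
        assert trend["trend_original_vs_time"].undefined
        assert trend["original_sources_mean"] == 0.0

    def test_hand_built_counts(self, make_contest):
        contest = make_contest(
            [
                ("e1", ["a", "b"], 4.0),
                ("e2", ["c"], 3.0),
                ("e3", ["a", "c", "d"], 2.0),
                ("e4", ["a", "c", "d"], 1.0),
            ]
        )
        trend = recombination_trend(contest)
        # original sources per entry: 0, 0, 2 (e1,e2), 3 (e1,e2,e3);
        # recent sources of e4 = 1: e3 carries all three lines most recently
        assert trend["original_sources_mean"] == pytest.approx(5 / 4)
        profiles = source_profiles(contest)
        assert [p.n_original_sources for p in profiles] == [0, 0, 2, 3]
        assert [p.n_recent_sources for p in profiles] == [0, 0, 2, 1]
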