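"""Leader timelines, increments, tweak/leap classification, correlations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codeculture.dynamics import (
    ClassificationConfig,
    classify_contest,
    compute_leader_timeline,
    log_transform_scores,
    rank_correlation,
    score_increments,
    tweak_leap_ratio,
)


class TestLeaderTimeline:
    def test_running_minimum(self, make_contest):
        contest = make_contest([("e1", ["a"], 5.0), ("e2", ["b"], 7.0), ("e3", ["c"], 3.0)])
        tl = compute_leader_timeline(contest)
        assert tl.leader_entry_ids == ["e1", "e1", "e3"]
        assert tl.leader_score.tolist() == [5.0, 5.0, 3.0]

    def test_ties_keep_incumbent(self, make_contest):
        contest = make_contest([("e1", ["a"], 5.0), ("e2", ["b"], 5.0)])
        tl = compute_leader_timeline(contest)
        assert tl.leader_entry_ids == ["e1", "e1"]

    @given(st.lists(st.integers(min_value=-50, max_value=50), min_size=1, max_size=100))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_prefix_argmin(self, scores):
        contest = _score_contest(scores)
        tl = compute_leader_timeline(contest)
        for i in range(len(scores)):
            prefix = scores[: i + 1]
            assert tl.leader_score[i] == min(prefix)
            assert tl.leader_index[i] == prefix.index(min(prefix))


def _score_contest(scores):
    from collections import Counter

    from codeculture.corpus import CanonicalEntry, Contest

    entries = [
        CanonicalEntry(
            contest_id="c1",
            entry_id=f"e{i:03d}",
            author_id="x",
            timestamp=float(i),
            score=float(s),
            phase="daylight",
            lines=Counter({f"line{i}": 1}),
        )
        for i, s in enumerate(scores)
    ]
    return Contest("c1", entries)


class TestLogTransform:
    def test_offset_applied(self):
        assert log_transform_scores([0.0]) == pytest.approx([math.log(10)])

    def test_zero_offset_identity_at_one(self):
        assert log_transform_scores([1.0], offset=0.0) == pytest.approx([0.0])

    def test_difference_of_logs(self):
        out = log_transform_scores([0.0, 90.0])
        assert out[1] - out[0] == pytest.approx(math.log(10))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            log_transform_scores([-20.0], offset=10.0)


class TestScoreIncrements:
    def test_minmax_normalisation(self):
        # deltas to running leader: e2:2, e3:6, e4:10
        contest = _score_contest([10, 12, 16, 20])
        incs = score_increments(contest)
        assert [i.raw_delta for i in incs] == [2.0, 6.0, 10.0]
        assert [i.normalised_delta for i in incs] == [0.0, 0.5, 1.0]

    def test_equal_to_leader_gives_zero(self):
        contest = _score_contest([10, 10, 11])
        incs = score_increments(contest)
        assert incs[0].raw_delta == 0.0 and incs[0].normalised_delta == 0.0

    def test_degenerate_range_returns_zeros(self, caplog):
        contest = _score_contest([10, 12, 12])  # all deltas = 2
        incs = score_increments(contest)
        assert all(i.normalised_delta == 0.0 for i in incs)


class TestClassification:
    @pytest.mark.parametrize(
        "similarity, mode, expected",
        [
            (0.95, "dual_threshold", "tweak"),
            (0.05, "dual_threshold", "leap"),
            (0.5, "dual_threshold", "unclassified"),
            (0.5, "single_cut", "tweak"),
            (0.49, "single_cut", "leap"),
        ],
    )
    def test_label_rules(self, similarity, mode, expected):
        config = ClassificationConfig(mode=mode)
        assert config.label(similarity) == expected

    def test_monotone_in_similarity(self):
        config = ClassificationConfig()
        rank = {"leap": 0, "unclassified": 1, "tweak": 2}
        labels = [rank[config.label(s)] for s in np.linspace(0, 1, 101)]
        assert labels == sorted(labels)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClassificationConfig(leap_below=0.9, tweak_above=0.1)

    def test_reference_is_leader_before_submission(self, make_contest):
        # e3 takes the lead; its reference is the previous leader e1
        contest = make_contest(
            [
                ("e1", {"a": 1, "b": 1}, 5.0),
                ("e2", {"c": 1}, 9.0),
                ("e3", {"a": 1, "b": 1}, 2.0),
            ]
        )
        labels = classify_contest(contest)
        by_id = {l.entry_id: l for l in labels}
        assert by_id["e3"].took_lead
        assert by_id["e3"].similarity_to_leader == 1.0  # vs e1, not e2
        assert not by_id["e2"].took_lead
        assert by_id["e2"].similarity_to_leader == 0.0

    def test_first_entry_excluded(self, make_contest):
        contest = make_contest([("e1", ["a"], 5.0), ("e2", ["a"], 6.0)])
        labels = classify_contest(contest)
        assert [l.entry_id for l in labels] == ["e2"]


class TestTweakLeapRatio:
    def _label(self, label, took_lead=False):
        from codeculture.dynamics import TweakLeapLabel

        return TweakLeapLabel("e", 0.5, label, took_lead, 0.0, 0.0)

    def test_direct_count(self):
        labels = [self._label("tweak"), self._label("tweak"), self._label("leap")]
        assert tweak_leap_ratio(labels).ratio == 2.0

    def test_all_tweaks_flagged_infinite(self):
        labels = [self._label("tweak")] * 3
        result = tweak_leap_ratio(labels)
        assert result.is_infinite and math.isinf(result.ratio)

    def test_leading_only_selection(self):
        labels = [
            self._label("tweak", took_lead=True),
            self._label("tweak"),
            self._label("leap", took_lead=True),
            self._label("leap"),
        ]
        r = tweak_leap_ratio(labels, leading_only=True)
        assert (r.n_tweaks, r.n_leaps) == (1, 1)


def brute_force_spearman(x, y):
    """Pearson correlation of average ranks, from the defining formula."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestRankCorrelation:
    def test_perfect_concordance(self):
        assert rank_correlation([1, 2, 3], [1, 2, 3]).rho == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert rank_correlation([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_constant_input_flagged(self):
        result = rank_correlation([1, 1, 1], [1, 2, 3])
        assert result.undefined and math.isnan(result.rho)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 5, size=10).astype(float)
        y = rng.integers(0, 5, size=10).astype(float)
        result = rank_correlation(x, y)
        assert result.rho == pytest.approx(brute_force_spearman(list(x), list(y)), abs=1e-12)
        assert 0 < result.p_value <= 1

    def test_large_sample_p_value(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        result = rank_correlation(x, y)
        assert result.rho > 0.5 and result.p_value < 1e-6
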