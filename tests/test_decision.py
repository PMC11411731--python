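from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from hospilink import (
    RunConfig,
    apply_city_filter,
    build_similarity_matrix,
    classify_continuity,
    link_cohorts,
    resolve_ties,
    select_linkages,
)
from hospilink.scoring import LinkageScore, SimilarityMatrix

from conftest import cohort, rec


def sm_from_pairs(pairs, ids1=None, ids2=None):
    """Build a SimilarityMatrix directly from (id1, id2, code, fwd, bwd, dist)."""
    scores = {
        (p[0], p[1]): LinkageScore(p[0], p[1], p[2], p[3], p[4], p[5])
        for p in pairs
    }
    ids1 = ids1 or sorted({p[0] for p in pairs})
    ids2 = ids2 or sorted({p[1] for p in pairs})
    return SimilarityMatrix(2016, 2017, ids1, ids2, scores)


class TestSelectLinkages:
    def test_unambiguous_perfect_pairs_all_accepted(self):
        sm = sm_from_pairs([
            ("A1", "B1", 4, 2, 2, 0.0),
            ("A2", "B2", 4, 2, 2, 0.0),
            ("A3", "B3", 4, 2, 2, 0.0),
        ])
        links = select_linkages(sm)
        assert set(links.accepted) == {("A1", "B1"), ("A2", "B2"), ("A3", "B3")}
        assert links.review_queue == []

    def test_highest_score_wins(self):
        sm = sm_from_pairs([
            ("A", "B1", 4, 1, 1, 2.0),   # total 6
            ("A", "B2", 4, 0, 0, 9.0),   # total 4
        ])
        links = select_linkages(sm)
        assert set(links.accepted) == {("A", "B1")}
        assert "B2" in links.unlinked_year2

    def test_tied_top_scores_go_to_review(self):
        sm = sm_from_pairs([
            ("A", "B1", 4, 1, 1, 2.0),
            ("A", "B2", 4, 1, 1, 3.0),
        ])
        links = select_linkages(sm)
        assert links.accepted == {}
        assert len(links.review_queue) == 1
        group = links.review_queue[0]
        assert group.facility_id == "A" and group.total == 6
        assert set(group.pairs) == {("A", "B1"), ("A", "B2")}
        # queued facility is neither accepted nor counted as plainly unlinked
        assert "A" not in links.unlinked_year1

    def test_tie_broken_when_competitor_endpoint_already_matched(self):
        # B2 is claimed at total 8 first; A's remaining total-6 candidate is unique
        sm = sm_from_pairs([
            ("C", "B2", 4, 2, 2, 0.0),   # total 8
            ("A", "B1", 4, 1, 1, 2.0),   # total 6
            ("A", "B2", 4, 1, 1, 2.0),   # total 6, endpoint taken
        ])
        links = select_linkages(sm)
        assert set(links.accepted) == {("C", "B2"), ("A", "B1")}
        assert links.review_queue == []

    def test_threshold_excludes_low_totals(self):
        sm = sm_from_pairs([("A", "B", 0, 1, 0, 5.0)])  # total 1
        links = select_linkages(sm, RunConfig(tolerance_threshold=2))
        assert links.accepted == {}
        assert links.unlinked_year1 == {"A"}

    def test_counting_identity(self):
        sm = sm_from_pairs(
            [
                ("A1", "B1", 4, 2, 2, 0.0),
                ("A2", "B2", 2, 1, 1, 1.0),
                ("A2", "B3", 2, 1, 1, 1.0),  # tie for A2
            ],
            ids1=["A1", "A2", "A9"],
            ids2=["B1", "B2", "B3", "B9"],
        )
        links = select_linkages(sm)
        assert len(links.accepted) + len(links.unlinked_year1) + len(links.queued_year1) == 3
        assert len(links.accepted) + len(links.unlinked_year2) + len(links.queued_year2) == 4

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        pairs = []
        for i in range(30):
            code = int(rng.choice([0, 2, 4]))
            f = int(rng.choice([0, 1, 2]))
            b = int(rng.choice([0, 1, 2]))
            if f == 2 or b == 2:
                f = b = 2  # keep scores on the valid lattice
            if code + f + b == 0:
                continue
            pairs.append((f"A{i % 12}", f"B{i % 17}", code, f, b, float(rng.uniform(0, 5))))
        sm = sm_from_pairs(list({(p[0], p[1]): p for p in pairs}.values()))
        counts = [
            len(select_linkages(sm, RunConfig(tolerance_threshold=t)).accepted)
            for t in range(1, 9)
        ]
        assert counts == sorted(counts, reverse=True)


def greedy_rule_oracle(sm, threshold):
    """Transcription of the decision rule, written independently of the
    implementation: scan candidates by (total desc, distance asc, ids);
    queue a facility when its top remaining candidates tie on total."""
    def keyf(s):
        d = s.distance_km if not math.isnan(s.distance_km) else float("inf")
        return (-s.total, d, s.id1, s.id2)

    remaining = sorted((s for s in sm.scores.values() if s.total >= threshold), key=keyf)
    accepted, m1, m2, q1, q2 = set(), set(), set(), set(), set()
    for s in remaining:
        if s.id1 in m1 or s.id2 in m2 or s.id1 in q1 or s.id2 in q2:
            continue
        rival1 = [
            t for t in remaining
            if t.id1 == s.id1 and t.id2 != s.id2 and t.total == s.total and t.id2 not in m2
        ]
        rival2 = [
            t for t in remaining
            if t.id2 == s.id2 and t.id1 != s.id1 and t.total == s.total and t.id1 not in m1
        ]
        if rival1:
            q1.add(s.id1)
        if rival2:
            q2.add(s.id2)
        if rival1 or rival2:
            continue
        accepted.add((s.id1, s.id2))
        m1.add(s.id1)
        m2.add(s.id2)
    return accepted, q1, q2


def test_selection_agrees_with_rule_oracle_on_random_instances():
    rng = np.random.default_rng(99)
    for _ in range(100):
        n1, n2 = int(rng.integers(1, 21)), int(rng.integers(1, 21))
        pairs = {}
        for _ in range(int(rng.integers(1, 60))):
            i, j = int(rng.integers(n1)), int(rng.integers(n2))
            code = int(rng.choice([0, 2, 4]))
            loc = int(rng.choice([0, 1, 2, 4]))
            f, b = (2, 2) if loc == 4 else ((1, 1) if loc == 2 else (loc, 0))
            if code + f + b == 0:
                continue
            pairs[(f"A{i}", f"B{j}")] = (
                f"A{i}", f"B{j}", code, f, b, float(rng.integers(0, 4)),
            )
        if not pairs:
            continue
        sm = sm_from_pairs(
            list(pairs.values()),
            ids1=[f"A{i}" for i in range(n1)],
            ids2=[f"B{j}" for j in range(n2)],
        )
        threshold = int(rng.integers(1, 5))
        links = select_linkages(sm, RunConfig(tolerance_threshold=threshold))
        accepted, q1, q2 = greedy_rule_oracle(sm, threshold)
        assert set(links.accepted) == accepted
        assert links.queued_year1 == q1 and links.queued_year2 == q2


def test_greedy_sum_never_exceeds_optimal_assignment():
    """Sanity: the greedy selection is bounded by the exhaustive best
    one-to-one matching (it equals it whenever no conflicts arise)."""
    rng = np.random.default_rng(17)
    for _ in range(30):
        n1, n2 = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        pairs = {}
        for _ in range(int(rng.integers(1, 10))):
            i, j = int(rng.integers(n1)), int(rng.integers(n2))
            total = int(rng.choice([1, 2, 3, 4, 5, 6, 8]))
            code = min(4, total - total % 2) if total != 8 else 4
            loc = total - code
            f, b = (2, 2) if loc == 4 else ((1, 1) if loc == 2 else (loc % 2, loc // 2))
            pairs[(f"A{i}", f"B{j}")] = (f"A{i}", f"B{j}", code, f, b, 1.0)
        sm = sm_from_pairs(list(pairs.values()))
        links = select_linkages(sm)
        greedy_sum = sum(s.total for s in links.accepted.values())
        ids1 = sorted({p[0] for p in pairs})
        ids2 = sorted({p[1] for p in pairs})
        small, large, flip = (
            (ids1, ids2, False) if len(ids1) <= len(ids2) else (ids2, ids1, True)
        )
        best = 0
        for perm in itertools.permutations(large, len(small)):
            total = 0
            for a, b in zip(small, perm):
                pair = (b, a) if flip else (a, b)
                if pair in sm.scores:
                    total += sm.scores[pair].total
            best = max(best, total)
        assert greedy_sum <= best


class TestCityFilter:
    def _links(self, mun2, required=True):
        c1 = cohort(2016, [rec("A", 2016, "X", municipality="Marburg")])
        c2 = cohort(2017, [rec("B", 2017, "X", municipality=mun2)])
        cfg = RunConfig(same_municipality_required=required)
        sm = build_similarity_matrix(c1, c2, cfg)
        links = select_linkages(sm, cfg)
        return apply_city_filter(links, c1, c2, cfg)

    def test_same_municipality_retained(self):
        links = self._links("Marburg")
        assert set(links.accepted) == {("A", "B")}

    def test_cross_city_pair_rejected_and_both_unlinked(self):
        links = self._links("Gießen")
        assert links.accepted == {}
        assert set(links.rejected_cross_city) == {("A", "B")}
        assert links.unlinked_year1 == {"A"} and links.unlinked_year2 == {"B"}

    def test_filter_disabled_is_identity(self):
        links = self._links("Gießen", required=False)
        assert set(links.accepted) == {("A", "B")}

    def test_missing_municipality_keeps_pair_with_warning(self):
        c1 = cohort(2016, [rec("A", 2016, "X", municipality=None)])
        c2 = cohort(2017, [rec("B", 2017, "X", municipality="Marburg")])
        cfg = RunConfig()
        sm = build_similarity_matrix(c1, c2, cfg)
        links = apply_city_filter(select_linkages(sm, cfg), c1, c2, cfg)
        assert set(links.accepted) == {("A", "B")}
        assert any("municipality missing" in w for w in links.warnings)


class TestContinuity:
    def test_total_eight_is_constant(self, single_pair_cohorts):
        sm, links, table = link_cohorts(*single_pair_cohorts)
        assert table.by_id("A", "year1").continuity_type == 1
        assert table.by_id("B", "year2").continuity_type == 1

    def test_total_below_eight_is_changed(self):
        c1 = cohort(2016, [rec("A", 2016, "X", sc="01")])
        c2 = cohort(2017, [rec("B", 2017, "X", sc="02")])
        _, _, table = link_cohorts(c1, c2)
        assert table.by_id("A", "year1").continuity_type == 2

    def test_unlinked_year_two_facility_is_newly_opened(self):
        c1 = cohort(2016, [rec("A", 2016, "X")])
        c2 = cohort(2017, [rec("B", 2017, "X"), rec("N", 2017, "Q", lat=54.0)])
        _, _, table = link_cohorts(c1, c2)
        assert table.by_id("N", "year2").continuity_type == 3

    def test_unlinked_year_one_facility_is_closed(self):
        c1 = cohort(2016, [rec("A", 2016, "X"), rec("G", 2016, "Q", lat=54.0)])
        c2 = cohort(2017, [rec("B", 2017, "X")])
        _, _, table = link_cohorts(c1, c2)
        assert table.by_id("G", "year1").continuity_type == 4

    def test_division_reconstructed_as_changed_plus_opened(self):
        # one year-one site, two plausible successors sharing its IIC;
        # the co-located one wins, the other is a new opening
        c1 = cohort(2016, [rec("A", 2016, "X", sc="01")])
        c2 = cohort(
            2017,
            [rec("B1", 2017, "X", sc="02"),
             rec("B2", 2017, "X", sc="03", lat=50.01)],
        )
        sm, links, table = link_cohorts(c1, c2)
        row_a = table.by_id("A", "year1")
        assert set(links.accepted) == {("A", "B1")}
        assert row_a.continuity_type == 2 and row_a.division_flag
        assert table.by_id("B2", "year2").continuity_type == 3

    def test_merge_flag_on_year_two_facility_with_multiple_candidates(self):
        c1 = cohort(
            2016,
            [rec("A1", 2016, "X", sc="01"), rec("A2", 2016, "X", sc="02", lat=50.01)],
        )
        c2 = cohort(2017, [rec("B", 2017, "X", sc="01")])
        _, links, table = link_cohorts(c1, c2)
        assert table.by_id("B", "year2").merge_flag
        assert table.by_id("A2", "year1").continuity_type == 4


class TestResolveTies:
    def _tied(self):
        sm = sm_from_pairs([
            ("A", "B1", 4, 1, 1, 2.0),
            ("A", "B2", 4, 1, 1, 2.0),
        ])
        return sm, select_linkages(sm)

    def test_resolution_moves_choice_to_accepted(self):
        sm, links = self._tied()
        links = resolve_ties(links, sm, {"A": ("A", "B2")})
        assert set(links.accepted) == {("A", "B2")}
        assert links.review_queue == []
        assert links.unlinked_year2 == {"B1"}

    def test_resolution_must_be_a_queued_candidate(self):
        sm, links = self._tied()
        with pytest.raises(ValueError, match="not a queued candidate"):
            resolve_ties(links, sm, {"A": ("A", "B9")})
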