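"""Linkage decisions: threshold, one-or-none selection, ties, city filter,
and continuity typing.

Each facility in either year ends up with at most one accepted linkage
("one linkage or none"). Among a facility's candidates the highest total
score wins; if the highest total is shared by several candidates the tie is
not resolved automatically — all tied pairs go to a review queue for manual
resolution, mirroring the manual checks the method prescribes. An accepted
linkage whose endpoints lie in different municipalities is discarded by the
city filter (a hospital does not move to another town and keep its
identity; such pairs are coincidental code or proximity matches).

Continuity types: 1 constant (linked, total 8), 2 changed (linked,
total < 8), 3 newly opened (year-two facility without linkage), 4 closed
(year-one facility without linkage). Divisions and mergers are
reconstructed as 2+3 and 2+4 respectively and surfaced as flags derived
from pre-selection candidate multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import RunConfig, YearCohort
from .scoring import LinkageScore, SimilarityMatrix

__all__ = [
    "TieGroup",
    "LinkSet",
    "ContinuityRow",
    "ContinuityTable",
    "select_linkages",
    "apply_city_filter",
    "classify_continuity",
    "resolve_ties",
]

CONTINUITY_CONSTANT = 1
CONTINUITY_CHANGED = 2
CONTINUITY_OPENED = 3
CONTINUITY_CLOSED = 4


@dataclass(frozen=True)
class TieGroup:
    """A facility whose top-scoring candidates tie and need manual review."""

    facility_id: str
    side: int  # 1 = year-one facility, 2 = year-two facility
    total: int
    pairs: tuple[tuple[str, str], ...]


@dataclass
class LinkSet:
    """Outcome of the linkage decision between two annual cohorts."""

    year1: int
    year2: int
    threshold: int
    accepted: dict[tuple[str, str], LinkageScore] = field(default_factory=dict)
    unlinked_year1: set[str] = field(default_factory=set)
    unlinked_year2: set[str] = field(default_factory=set)
    review_queue: list[TieGroup] = field(default_factory=list)
    rejected_cross_city: dict[tuple[str, str], LinkageScore] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def queued_year1(self) -> set[str]:
        return {g.facility_id for g in self.review_queue if g.side == 1}

    @property
    def queued_year2(self) -> set[str]:
        return {g.facility_id for g in self.review_queue if g.side == 2}

    def partner_of_year1(self, record_id: str) -> LinkageScore | None:
        for s in self.accepted.values():
            if s.id1 == record_id:
                return s
        return None

    def validate(self) -> None:
        """Check the one-or-none invariant; raises AssertionError on violation."""
        ids1 = [p[0] for p in self.accepted]
        ids2 = [p[1] for p in self.accepted]
        assert len(ids1) == len(set(ids1)), "a year-one facility holds two linkages"
        assert len(ids2) == len(set(ids2)), "a year-two facility holds two linkages"
        assert not set(self.accepted) & set(self.rejected_cross_city)


def _sort_key(s: LinkageScore) -> tuple:
    d = s.distance_km if not math.isnan(s.distance_km) else float("inf")
    return (-s.total, d, s.id1, s.id2)


def select_linkages(sm: SimilarityMatrix, config: RunConfig | None = None) -> LinkSet:
    """Greedy one-or-none selection over the similarity matrix.

    Candidate pairs at or above the tolerance threshold are scanned in
    deterministic order (total descending, then distance ascending, then
    lexicographic ids). A pair is accepted when neither endpoint is already
    matched or queued. Before accepting, each endpoint is checked for
    competing still-available candidates with the *same* total: such a tie
    on the score cannot be resolved automatically, so all tied pairs for
    that endpoint form a :class:`TieGroup` and the facility is left
    provisionally unlinked pending review.
    """
    config = config or RunConfig()
    threshold = int(config.tolerance_threshold)

    candidates = sorted(
        (s for s in sm.scores.values() if s.total >= threshold), key=_sort_key
    )
    matched1: set[str] = set()
    matched2: set[str] = set()
    queued1: set[str] = set()
    queued2: set[str] = set()
    links = LinkSet(sm.year1, sm.year2, threshold)

    def competitors(s: LinkageScore, side: int) -> list[LinkageScore]:
        """Other viable candidates of s's side-`side` endpoint at the same total."""
        if side == 1:
            pool = sm.candidates_for(s.id1, 1)
            return [
                q
                for q in pool
                if q.pair != s.pair
                and q.total == s.total
                and q.total >= threshold
                and q.id2 not in matched2
            ]
        pool = sm.candidates_for(s.id2, 2)
        return [
            q
            for q in pool
            if q.pair != s.pair
            and q.total == s.total
            and q.total >= threshold
            and q.id1 not in matched1
        ]

    for s in candidates:
        if s.id1 in matched1 or s.id2 in matched2:
            continue
        if s.id1 in queued1 or s.id2 in queued2:
            continue
        tied = False
        comp1 = competitors(s, 1)
        if comp1:
            group = sorted([s] + comp1, key=_sort_key)
            links.review_queue.append(
                TieGroup(s.id1, 1, s.total, tuple(q.pair for q in group))
            )
            queued1.add(s.id1)
            tied = True
        comp2 = competitors(s, 2)
        if comp2:
            group = sorted([s] + comp2, key=_sort_key)
            links.review_queue.append(
                TieGroup(s.id2, 2, s.total, tuple(q.pair for q in group))
            )
            queued2.add(s.id2)
            tied = True
        if tied:
            continue
        links.accepted[s.pair] = s
        matched1.add(s.id1)
        matched2.add(s.id2)

    links.unlinked_year1 = set(sm.ids1) - matched1 - queued1
    links.unlinked_year2 = set(sm.ids2) - matched2 - queued2
    links.validate()
    return links


def apply_city_filter(
    links: LinkSet,
    cohort1: YearCohort,
    cohort2: YearCohort,
    config: RunConfig | None = None,
) -> LinkSet:
    """Discard accepted linkages that cross a city/town boundary.

    Municipality names are compared after normalization. A pair with a
    missing municipality on either side is kept with a warning (the filter
    cannot be evaluated). Freed endpoints become unlinked and are *not*
    re-offered their next-best candidate (single-pass semantics). No-op
    when ``same_municipality_required`` is off.
    """
    config = config or RunConfig()
    if not config.same_municipality_required:
        return links

    for pair in list(links.accepted):
        id1, id2 = pair
        m1 = cohort1[id1].municipality_norm
        m2 = cohort2[id2].municipality_norm
        if m1 is None or m2 is None:
            links.warnings.append(
                f"city filter skipped for {id1}<->{id2}: municipality missing"
            )
            continue
        if m1 != m2:
            links.rejected_cross_city[pair] = links.accepted.pop(pair)
            links.unlinked_year1.add(id1)
            links.unlinked_year2.add(id2)
    links.validate()
    return links


def resolve_ties(
    links: LinkSet, sm: SimilarityMatrix, resolutions: dict[str, tuple[str, str]]
) -> LinkSet:
    """Merge manual tie resolutions into the link set.

    ``resolutions`` maps a queued facility id to the chosen (id1, id2) pair.
    A resolution is applied only if it is one of the queued candidates and
    does not violate one-or-none against already-accepted pairs.
    """
    remaining: list[TieGroup] = []
    matched1 = {p[0] for p in links.accepted}
    matched2 = {p[1] for p in links.accepted}
    for group in links.review_queue:
        choice = resolutions.get(group.facility_id)
        if choice is None:
            remaining.append(group)
            continue
        if choice not in group.pairs:
            raise ValueError(
                f"resolution {choice} for {group.facility_id} is not a queued candidate"
            )
        if choice[0] in matched1 or choice[1] in matched2:
            raise ValueError(f"resolution {choice} conflicts with an accepted linkage")
        score = sm.get(*choice)
        assert score is not None
        links.accepted[choice] = score
        matched1.add(choice[0])
        matched2.add(choice[1])
        links.unlinked_year1.discard(choice[0])
        links.unlinked_year2.discard(choice[1])
    links.review_queue = remaining
    links.unlinked_year1 = set(sm.ids1) - matched1 - links.queued_year1
    links.unlinked_year2 = set(sm.ids2) - matched2 - links.queued_year2
    links.validate()
    return links


@dataclass(frozen=True)
class ContinuityRow:
    record_id: str
    year: int
    role: str  # "year1" | "year2"
    continuity_type: int
    division_flag: bool
    merge_flag: bool
    pending_review: bool
    partner_id: str | None
    total: int | None


@dataclass
class ContinuityTable:
    rows: list[ContinuityRow]

    def by_id(self, record_id: str, role: str) -> ContinuityRow:
        for r in self.rows:
            if r.record_id == record_id and r.role == role:
                return r
        raise KeyError((record_id, role))

    def counts(self) -> dict[int, int]:
        out: dict[int, int] = {1: 0, 2: 0, 3: 0, 4: 0}
        for r in self.rows:
            out[r.continuity_type] += 1
        return out


def classify_continuity(links: LinkSet, sm: SimilarityMatrix) -> ContinuityTable:
    """Assign continuity types to every facility of both cohorts.

    Division/merge flags record pre-selection candidate multiplicity: a
    year-one facility with two or more above-threshold candidates may have
    divided (its accepted linkage is the continuing part, the unmatched
    candidate a new opening); symmetric for mergers on the year-two side.
    """
    threshold = links.threshold
    accepted_by_1 = {p[0]: s for p, s in links.accepted.items()}
    accepted_by_2 = {p[1]: s for p, s in links.accepted.items()}
    queued1, queued2 = links.queued_year1, links.queued_year2

    def multiplicity(record_id: str, side: int) -> int:
        return sum(
            1 for s in sm.candidates_for(record_id, side) if s.total >= threshold
        )

    rows: list[ContinuityRow] = []
    for rid in sm.ids1:
        s = accepted_by_1.get(rid)
        if s is not None:
            ctype = CONTINUITY_CONSTANT if s.total == 8 else CONTINUITY_CHANGED
        else:
            ctype = CONTINUITY_CLOSED
        rows.append(
            ContinuityRow(
                record_id=rid,
                year=links.year1,
                role="year1",
                continuity_type=ctype,
                division_flag=multiplicity(rid, 1) >= 2,
                merge_flag=False,
                pending_review=rid in queued1,
                partner_id=s.id2 if s else None,
                total=s.total if s else None,
            )
        )
    for rid in sm.ids2:
        s = accepted_by_2.get(rid)
        if s is not None:
            ctype = CONTINUITY_CONSTANT if s.total == 8 else CONTINUITY_CHANGED
        else:
            ctype = CONTINUITY_OPENED
        rows.append(
            ContinuityRow(
                record_id=rid,
                year=links.year2,
                role="year2",
                continuity_type=ctype,
                division_flag=False,
                merge_flag=multiplicity(rid, 2) >= 2,
                pending_review=rid in queued2,
                partner_id=s.id1 if s else None,
                total=s.total if s else None,
            )
        )
    return ContinuityTable(rows)
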