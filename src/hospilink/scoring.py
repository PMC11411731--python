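"""Similarity scoring between two annual cohorts.

Each candidate pair (year-one record, year-two record) receives a total
score that is the sum of two sub-scores:

* the *code sub-score* compares the administrative identification code —
  4 for identical IIC and SC, 2 for identical IIC with differing SC,
  0 for different IIC (under ``sc_mode="iic_only"``: 4 for identical IIC,
  else 0);

* the *location sub-score* is rank-based: a forward component of 2 if the
  year-two record is the year-one record's nearest counterpart at snapped
  distance zero, 1 if nearest at positive distance, 0 otherwise, plus the
  symmetric backward component. Attainable values are therefore
  {0, 1, 2, 4} — a pair at distance zero is necessarily nearest in both
  directions, so 2+1 = 3 cannot occur.

Total scores live on the lattice {0, 1, 2, 3, 4, 5, 6, 8}; 8 means no
change in either key variable and 7 is unattainable. Only pairs with a
positive total are stored (the similarity matrix is sparse: almost all
cross-pairs score 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geo import DistanceMatrix, EmptyCohortError, distance_matrix
from .model import FacilityRecord, RunConfig, YearCohort

__all__ = [
    "LinkageScore",
    "SimilarityMatrix",
    "code_subscore",
    "location_subscores",
    "build_similarity_matrix",
]


def code_subscore(a: FacilityRecord, b: FacilityRecord, mode: str = "full") -> int:
    """Administrative-code sub-score: 4, 2 or 0.

    Under ``mode="full"`` an absent SC on either side compares as a
    *different* SC (identity of the site cannot be confirmed), yielding 2
    when the IICs agree.
    """
    if not a.iic or not b.iic:
        raise ValueError("code_subscore requires an IIC on both records")
    if a.iic != b.iic:
        return 0
    if mode == "iic_only":
        return 4
    if mode != "full":
        raise ValueError(f"unknown sc_mode {mode!r}")
    sa, sb = a.sc_norm, b.sc_norm
    if sa is not None and sa == sb:
        return 4
    return 2


def location_subscores(dm: DistanceMatrix) -> dict[tuple[str, str], tuple[int, int]]:
    """Forward/backward location components for every pair with a positive sum.

    A pair's forward component is 2 when the year-two record is in the
    year-one record's nearest set at zero distance, 1 when in the nearest
    set at positive distance; the backward component is symmetric. Only
    pairs where either component is positive are returned.
    """
    comps: dict[tuple[str, str], tuple[int, int]] = {}
    for rid, nearest in dm.row_argmin.items():
        score = 2 if dm.row_min[rid] == 0.0 else 1
        for cid in nearest:
            comps[(rid, cid)] = (score, 0)
    for cid, nearest in dm.col_argmin.items():
        score = 2 if dm.col_min[cid] == 0.0 else 1
        for rid in nearest:
            f, _ = comps.get((rid, cid), (0, 0))
            comps[(rid, cid)] = (f, score)
    return comps


@dataclass(frozen=True)
class LinkageScore:
    """Full score decomposition of one candidate pair."""

    id1: str
    id2: str
    code: int
    forward: int
    backward: int
    distance_km: float  # NaN when either record lacks coordinates

    @property
    def location(self) -> int:
        return self.forward + self.backward

    @property
    def total(self) -> int:
        return self.code + self.forward + self.backward

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id1, self.id2)


@dataclass
class SimilarityMatrix:
    """Sparse pairwise scores between two annual cohorts.

    Stores every pair with a positive total, indexed by either endpoint,
    plus the complete id lists of both cohorts (needed downstream to
    enumerate unlinked facilities).
    """

    year1: int
    year2: int
    ids1: list[str]
    ids2: list[str]
    scores: dict[tuple[str, str], LinkageScore] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.by_id1: dict[str, list[LinkageScore]] = {}
        self.by_id2: dict[str, list[LinkageScore]] = {}
        for s in self.scores.values():
            self.by_id1.setdefault(s.id1, []).append(s)
            self.by_id2.setdefault(s.id2, []).append(s)

    def __len__(self) -> int:
        return len(self.scores)

    def get(self, id1: str, id2: str) -> LinkageScore | None:
        return self.scores.get((id1, id2))

    def candidates_for(self, record_id: str, side: int) -> list[LinkageScore]:
        """All stored pairs touching ``record_id`` on cohort side 1 or 2."""
        index = self.by_id1 if side == 1 else self.by_id2
        return list(index.get(record_id, []))


def build_similarity_matrix(
    cohort1: YearCohort, cohort2: YearCohort, config: RunConfig | None = None
) -> SimilarityMatrix:
    """Score all cross-pairs of two cohorts and keep those with total > 0.

    Candidate pairs arise from two sparse sources: pairs sharing an IIC
    (positive code sub-score) and pairs in a nearest-neighbor relation
    (positive location sub-score); everything else scores 0 and is omitted.
    """
    if len(cohort1) == 0 or len(cohort2) == 0:
        raise EmptyCohortError("build_similarity_matrix requires two non-empty cohorts")
    config = config or RunConfig()

    dm = distance_matrix(cohort1, cohort2, config)
    loc = location_subscores(dm)

    # pairs with a shared IIC, via an index rather than an n^2 scan
    by_iic2: dict[str, list[FacilityRecord]] = {}
    for rec in cohort2:
        by_iic2.setdefault(rec.iic, []).append(rec)
    code_pairs: dict[tuple[str, str], int] = {}
    for a in cohort1:
        for b in by_iic2.get(a.iic, ()):
            code_pairs[(a.record_id, b.record_id)] = code_subscore(a, b, config.sc_mode)

    scores: dict[tuple[str, str], LinkageScore] = {}
    for pair in code_pairs.keys() | loc.keys():
        code = code_pairs.get(pair, 0)
        f, b = loc.get(pair, (0, 0))
        if code + f + b <= 0:
            continue
        scores[pair] = LinkageScore(
            id1=pair[0],
            id2=pair[1],
            code=code,
            forward=f,
            backward=b,
            distance_km=dm.distance(*pair),
        )
    return SimilarityMatrix(cohort1.year, cohort2.year, cohort1.ids, cohort2.ids, scores)
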