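"""Evaluation against reference linkages, the code-only baseline, and
variable profiling.

The quality accounting follows the standard true / false / missed match
decomposition: given a gold standard of correct linkages, a method's true
matches are the accepted pairs that appear in gold, false matches the
accepted pairs that do not, and missed matches the gold pairs the method
failed to recover. The success rate is true matches over the gold total,
so true + missed = total always holds; false matches are reported
separately and do not enter the denominator.

The baseline linker reproduces the naive approach of linking on identical
administrative codes alone, which breaks down whenever site codes are
renumbered — precisely the failure mode the similarity-matrix method is
designed to survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .decision import LinkSet
from .model import YearCohort
from .scoring import LinkageScore

__all__ = [
    "GoldStandard",
    "EvaluationReport",
    "VariableProfile",
    "baseline_code_linker",
    "score_against_gold",
    "profile_variable",
]


@dataclass
class GoldStandard:
    """Reference linkages (a partial matching) between two annual cohorts."""

    pairs: list[tuple[str, str]]
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids1 = [p[0] for p in self.pairs]
        ids2 = [p[1] for p in self.pairs]
        if len(ids1) != len(set(ids1)) or len(ids2) != len(set(ids2)):
            raise ValueError("gold standard is not a partial matching (an id repeats)")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)


@dataclass(frozen=True)
class EvaluationReport:
    total_linkage_number: int
    true_matches: int
    false_matches: int
    missed_matches: int

    def __post_init__(self) -> None:
        assert self.true_matches + self.missed_matches == self.total_linkage_number

    def _rate(self, count: int) -> float:
        if self.total_linkage_number == 0:
            return float("nan")
        return 100.0 * count / self.total_linkage_number

    @property
    def true_rate(self) -> float:
        """Success rate in percent: recovered share of the gold linkages."""
        return self._rate(self.true_matches)

    @property
    def false_rate(self) -> float:
        return self._rate(self.false_matches)

    @property
    def missed_rate(self) -> float:
        return self._rate(self.missed_matches)

    def to_dict(self) -> dict:
        return {
            "total_linkage_number": self.total_linkage_number,
            "true_matches": self.true_matches,
            "true_rate_pct": round(self.true_rate, 1),
            "false_matches": self.false_matches,
            "false_rate_pct": round(self.false_rate, 1),
            "missed_matches": self.missed_matches,
            "missed_rate_pct": round(self.missed_rate, 1),
        }


def baseline_code_linker(
    cohort1: YearCohort, cohort2: YearCohort, mode: str = "full"
) -> LinkSet:
    """Link purely on identical administrative codes.

    ``mode="full"`` matches on (IIC, normalized SC); ``mode="iic_only"``
    on IIC alone. A code value occurring more than once on either side is
    ambiguous: all its records are left unlinked and a warning is logged.
    """
    if mode not in ("full", "iic_only"):
        raise ValueError(f"unknown sc_mode {mode!r}")

    def key(rec):
        return (rec.iic, rec.sc_norm) if mode == "full" else rec.iic

    by1: dict[object, list[str]] = {}
    by2: dict[object, list[str]] = {}
    for rec in cohort1:
        by1.setdefault(key(rec), []).append(rec.record_id)
    for rec in cohort2:
        by2.setdefault(key(rec), []).append(rec.record_id)

    links = LinkSet(cohort1.year, cohort2.year, threshold=1)
    matched1: set[str] = set()
    matched2: set[str] = set()
    for k, ids1 in by1.items():
        ids2 = by2.get(k)
        if ids2 is None:
            continue
        if len(ids1) > 1 or len(ids2) > 1:
            links.warnings.append(
                f"ambiguous code {k!r}: {len(ids1)} year-one vs {len(ids2)} "
                "year-two records left unlinked"
            )
            continue
        pair = (ids1[0], ids2[0])
        links.accepted[pair] = LinkageScore(
            id1=pair[0], id2=pair[1], code=4, forward=0, backward=0,
            distance_km=float("nan"),
        )
        matched1.add(pair[0])
        matched2.add(pair[1])
    links.unlinked_year1 = set(cohort1.ids) - matched1
    links.unlinked_year2 = set(cohort2.ids) - matched2
    links.validate()
    return links


def score_against_gold(links: LinkSet, gold: GoldStandard) -> EvaluationReport:
    """True / false / missed match counts of a link set against gold."""
    accepted = set(links.accepted)
    gold_set = gold.pair_set
    true = len(accepted & gold_set)
    false = len(accepted - gold_set)
    missed = len(gold_set - accepted)
    return EvaluationReport(
        total_linkage_number=len(gold_set),
        true_matches=true,
        false_matches=false,
        missed_matches=missed,
    )


@dataclass(frozen=True)
class VariableProfile:
    """Profiling statistics guiding key-variable selection.

    ``distinction`` counts distinct values per year (a good key variable
    nearly separates all records); ``value_stability`` counts, per adjacent
    year pair, how many matched records kept the same value (a good key
    variable rarely changes on true links).
    """

    variable: str
    distinction: dict[int, int]
    value_stability: dict[tuple[int, int], int]


def _value_of(rec, variable: str):
    if variable in ("iic", "sc", "municipality", "record_id"):
        v = getattr(rec, variable)
    elif variable == "coord":
        v = (rec.lat, rec.lon) if rec.has_coord else None
    elif variable in rec.attributes:
        v = rec.attributes[variable]
    else:
        raise KeyError(variable)
    return v


def profile_variable(
    cohorts: Sequence[YearCohort],
    variable: str,
    golds: Sequence[GoldStandard] | None = None,
) -> VariableProfile:
    """Distinct-value and stability counts for one variable across years.

    Stability is computed over matched record pairs of adjacent years:
    matches come from ``golds`` (one per adjacent pair) when given,
    otherwise from exact (IIC, SC) code equality.
    """
    for cohort in cohorts:
        for rec in cohort:
            try:
                _value_of(rec, variable)
            except KeyError:
                raise KeyError(
                    f"variable {variable!r} not resolvable on record {rec.record_id!r}"
                ) from None

    distinction = {
        c.year: len({_value_of(r, variable) for r in c}) for c in cohorts
    }

    stability: dict[tuple[int, int], int] = {}
    for i, (c1, c2) in enumerate(zip(cohorts, cohorts[1:])):
        if golds is not None:
            pairs = golds[i].pairs
        else:
            code2 = {(r.iic, r.sc_norm): r.record_id for r in c2}
            pairs = [
                (r.record_id, code2[(r.iic, r.sc_norm)])
                for r in c1
                if (r.iic, r.sc_norm) in code2
            ]
        stability[(c1.year, c2.year)] = sum(
            1
            for id1, id2 in pairs
            if _value_of(c1[id1], variable) == _value_of(c2[id2], variable)
        )
    return VariableProfile(variable, distinction, stability)
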