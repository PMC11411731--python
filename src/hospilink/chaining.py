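"""Assembling pairwise link sets into a longitudinal panel.

Linkage is decided between adjacent years only; the panel chains those
decisions into stable longitudinal identifiers. A facility linked through
every transition keeps one id for the whole window; an unlinked facility
terminates its chain (closure) or starts a fresh one (opening). No gap
bridging is performed: a facility absent in an intermediate year and
reappearing later gets a new longitudinal id, otherwise the pairwise
opening/closure accounting would silently be contradicted.

The longitudinal id is ``"<first year>:<first record id>"``, reproducible
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .decision import LinkSet

__all__ = ["PanelRow", "PanelTable", "chain_linkages"]


class ChainConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PanelRow:
    longitudinal_id: str
    year: int
    record_id: str
    #: total score of the accepted linkage *into* this year (None for the
    #: first year of the chain)
    in_score: int | None


@dataclass
class PanelTable:
    years: list[int]
    rows: list[PanelRow] = field(default_factory=list)

    def membership(self) -> dict[str, dict[int, str]]:
        """longitudinal_id -> {year: record_id}."""
        out: dict[str, dict[int, str]] = {}
        for r in self.rows:
            out.setdefault(r.longitudinal_id, {})[r.year] = r.record_id
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "longitudinal_id": r.longitudinal_id,
                    "year": r.year,
                    "record_id": r.record_id,
                    "in_score": r.in_score,
                }
                for r in self.rows
            ],
            columns=["longitudinal_id", "year", "record_id", "in_score"],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def chain_linkages(linksets: Sequence[LinkSet]) -> PanelTable:
    """Chain consecutive pairwise link sets into longitudinal identifiers.

    ``linksets`` must cover consecutive year pairs (the second year of each
    equals the first year of the next). Chains follow accepted linkages
    only; queued (unresolved tie) facilities count as unlinked.
    """
    if not linksets:
        raise ChainConfigurationError("at least one LinkSet is required")
    for prev, nxt in zip(linksets, linksets[1:]):
        if prev.year2 != nxt.year1:
            raise ChainConfigurationError(
                f"link sets are not consecutive: {prev.year1}-{prev.year2} "
                f"followed by {nxt.year1}-{nxt.year2}"
            )
    years = [linksets[0].year1] + [ls.year2 for ls in linksets]

    # (year, record_id) -> (longitudinal_id, score into that year)
    lid_of: dict[tuple[int, str], tuple[str, int | None]] = {}

    def all_ids(year_index: int) -> list[str]:
        if year_index == 0:
            ls = linksets[0]
            ids = {p[0] for p in ls.accepted} | ls.unlinked_year1 | ls.queued_year1
            ids |= {p[0] for p in ls.rejected_cross_city}
            return sorted(ids)
        ls = linksets[year_index - 1]
        ids = {p[1] for p in ls.accepted} | ls.unlinked_year2 | ls.queued_year2
        ids |= {p[1] for p in ls.rejected_cross_city}
        return sorted(ids)

    for rid in all_ids(0):
        lid_of[(years[0], rid)] = (f"{years[0]}:{rid}", None)

    for k, ls in enumerate(linksets):
        y1, y2 = years[k], years[k + 1]
        forward = {p[0]: (p[1], s.total) for p, s in ls.accepted.items()}
        linked2: set[str] = set()
        for rid1, (rid2, total) in forward.items():
            key = (y1, rid1)
            if key not in lid_of:  # facility not seen in y1 enumeration
                lid_of[key] = (f"{y1}:{rid1}", None)
            lid_of[(y2, rid2)] = (lid_of[key][0], total)
            linked2.add(rid2)
        for rid2 in all_ids(k + 1):
            if rid2 not in linked2:
                lid_of[(y2, rid2)] = (f"{y2}:{rid2}", None)

    rows = [
        PanelRow(longitudinal_id=lid, year=year, record_id=rid, in_score=score)
        for (year, rid), (lid, score) in sorted(
            lid_of.items(), key=lambda kv: (kv[1][0], kv[0][0])
        )
    ]
    return PanelTable(years=years, rows=rows)
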