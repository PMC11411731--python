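"""Reading and writing cohort, linkage, gold-standard and config files.

All tabular formats are plain UTF-8 CSV with a header row. Cohort files
carry one row per hospital site; column names are configurable through a
schema mapping so arbitrary source exports can be ingested without
renaming. Coordinates are decimal degrees (five or more decimals
recommended — one degree of latitude is ~111 km, so five decimals resolve
to ~1 m, well below the zero-distance epsilon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .decision import LinkSet, TieGroup
from .model import FacilityRecord, RunConfig, YearCohort
from .scoring import LinkageScore

__all__ = [
    "ConfigurationError",
    "CohortParseError",
    "Diagnostic",
    "DEFAULT_SCHEMA",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "write_linkages",
    "read_linkages",
    "write_similarity_csv",
    "write_continuity_csv",
    "read_gold_csv",
    "write_gold_csv",
    "load_config",
    "save_config",
]


class ConfigurationError(ValueError):
    pass


class CohortParseError(ValueError):
    pass


#: standard field -> default CSV column name
DEFAULT_SCHEMA: dict[str, str] = {
    "record_id": "record_id",
    "iic": "iic",
    "sc": "sc",
    "lat": "lat",
    "lon": "lon",
    "municipality": "municipality",
}

_REQUIRED = ("record_id", "iic", "lat", "lon", "municipality")


def _float_or_none(v) -> float | None:
    if v is None:
        return None
    s = str(v).strip()
    if not s:
        return None
    return float(s)


def read_cohort(
    path: str | Path, year: int, schema: Mapping[str, str] | None = None
) -> YearCohort:
    """Read one annual cohort from CSV.

    ``schema`` maps standard field names (record_id, iic, sc, lat, lon,
    municipality) to the file's column names; unmapped extra columns are
    kept as descriptive attributes. The sc column is optional. Rows whose
    coordinates cannot be parsed or lie outside the valid range are
    rejected with a diagnostic listing every offending row.
    """
    eff = dict(DEFAULT_SCHEMA)
    eff.update(schema or {})

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        raise CohortParseError(f"{path}: empty file")

    missing = [eff[k] for k in _REQUIRED if eff[k] not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required columns {missing}")
    has_sc = eff["sc"] in df.columns
    if df.empty:
        raise CohortParseError(f"{path}: no data rows")

    std_cols = {eff[k] for k in eff if eff[k] in df.columns}
    attr_cols = [c for c in df.columns if c not in std_cols]

    records: list[FacilityRecord] = []
    bad_rows: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        rid = str(row_d[eff["record_id"]]).strip()
        try:
            lat = _float_or_none(row_d[eff["lat"]])
            lon = _float_or_none(row_d[eff["lon"]])
            sc = str(row_d[eff["sc"]]).strip() or None if has_sc else None
            rec = FacilityRecord(
                record_id=rid,
                year=year,
                iic=str(row_d[eff["iic"]]).strip(),
                sc=sc,
                lat=lat,
                lon=lon,
                municipality=str(row_d[eff["municipality"]]).strip() or None,
                attributes={c: row_d[c] for c in attr_cols},
            )
        except ValueError as exc:
            bad_rows.append(f"row {i + 2} (id={rid!r}): {exc}")
            continue
        records.append(rec)

    if bad_rows:
        raise CohortParseError(
            f"{path}: {len(bad_rows)} unparseable row(s):\n" + "\n".join(bad_rows)
        )
    return YearCohort(year=year, records=records)


def write_cohort(cohort: YearCohort, path: str | Path) -> None:
    attr_cols = sorted({k for rec in cohort for k in rec.attributes})
    rows = []
    for rec in cohort:
        row = {
            "record_id": rec.record_id,
            "iic": rec.iic,
            "sc": rec.sc if rec.sc is not None else "",
            "lat": f"{rec.lat:.6f}" if rec.has_coord else "",
            "lon": f"{rec.lon:.6f}" if rec.has_coord else "",
            "municipality": rec.municipality or "",
        }
        for c in attr_cols:
            row[c] = rec.attributes.get(c, "")
        rows.append(row)
    cols = list(DEFAULT_SCHEMA.values()) + attr_cols
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


@dataclass(frozen=True)
class Diagnostic:
    kind: str  # duplicate_code | co_located_different_iic | missing_municipality | missing_coordinates
    message: str
    record_ids: tuple[str, ...]


def validate_cohort(cohort: YearCohort) -> list[Diagnostic]:
    """Non-mutating data-quality report for one cohort.

    Flags duplicate (IIC, SC) pairs, records sharing exact coordinates under
    different IICs (a typical sign of address input errors), and missing
    municipality or coordinate values. Output order is deterministic.
    """
    diags: list[Diagnostic] = []

    by_code: dict[tuple[str, str | None], list[str]] = {}
    for rec in cohort:
        by_code.setdefault((rec.iic, rec.sc_norm), []).append(rec.record_id)
    for (iic, sc), ids in sorted(by_code.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")):
        if len(ids) > 1:
            diags.append(
                Diagnostic(
                    "duplicate_code",
                    f"(IIC={iic}, SC={sc}) shared by {len(ids)} records",
                    tuple(ids),
                )
            )

    by_coord: dict[tuple[float, float], list[FacilityRecord]] = {}
    for rec in cohort:
        if rec.has_coord:
            by_coord.setdefault((rec.lat, rec.lon), []).append(rec)
    for coord, recs in sorted(by_coord.items()):
        if len(recs) > 1 and len({r.iic for r in recs}) > 1:
            diags.append(
                Diagnostic(
                    "co_located_different_iic",
                    f"coordinate {coord} shared by records with different IICs",
                    tuple(r.record_id for r in recs),
                )
            )

    missing_mun = tuple(r.record_id for r in cohort if r.municipality_norm is None)
    if missing_mun:
        diags.append(
            Diagnostic(
                "missing_municipality",
                f"{len(missing_mun)} record(s) without municipality",
                missing_mun,
            )
        )
    missing_coord = tuple(r.record_id for r in cohort if not r.has_coord)
    if missing_coord:
        diags.append(
            Diagnostic(
                "missing_coordinates",
                f"{len(missing_coord)} record(s) without coordinates",
                missing_coord,
            )
        )
    return diags


_LINK_COLS = [
    "status",
    "year1",
    "year2",
    "threshold",
    "id1",
    "id2",
    "code_subscore",
    "forward",
    "backward",
    "location_subscore",
    "total",
    "distance_km",
    "group_id",
    "side",
]


def _score_row(status: str, links: LinkSet, s: LinkageScore, **extra) -> dict:
    return {
        "status": status,
        "year1": links.year1,
        "year2": links.year2,
        "threshold": links.threshold,
        "id1": s.id1,
        "id2": s.id2,
        "code_subscore": s.code,
        "forward": s.forward,
        "backward": s.backward,
        "location_subscore": s.location,
        "total": s.total,
        "distance_km": "" if math.isnan(s.distance_km) else repr(s.distance_km),
        **extra,
    }


def write_linkages(links: LinkSet, path: str | Path) -> None:
    """Serialize a LinkSet to CSV: one row per accepted linkage, per
    unlinked facility, per queued tie candidate and per city-filter
    rejection, in a fixed column order."""
    rows: list[dict] = []
    for s in sorted(links.accepted.values(), key=lambda s: (s.id1, s.id2)):
        rows.append(_score_row("accepted", links, s))
    for s in sorted(links.rejected_cross_city.values(), key=lambda s: (s.id1, s.id2)):
        rows.append(_score_row("rejected_cross_city", links, s))
    for gid, group in enumerate(links.review_queue):
        for id1, id2 in group.pairs:
            rows.append(
                {
                    "status": "queued",
                    "year1": links.year1,
                    "year2": links.year2,
                    "threshold": links.threshold,
                    "id1": id1,
                    "id2": id2,
                    "total": group.total,
                    "group_id": gid,
                    "side": group.side,
                }
            )
    for rid in sorted(links.unlinked_year1):
        rows.append(
            {
                "status": "unlinked",
                "year1": links.year1,
                "year2": links.year2,
                "threshold": links.threshold,
                "id1": rid,
            }
        )
    for rid in sorted(links.unlinked_year2):
        rows.append(
            {
                "status": "unlinked",
                "year1": links.year1,
                "year2": links.year2,
                "threshold": links.threshold,
                "id2": rid,
            }
        )
    # all-string cells: mixed int/empty columns must not become floats
    df = pd.DataFrame(
        [{c: ("" if r.get(c) is None else str(r.get(c, ""))) for c in _LINK_COLS} for r in rows],
        columns=_LINK_COLS,
    )
    df.to_csv(path, index=False)


def read_linkages(path: str | Path) -> LinkSet:
    """Inverse of :func:`write_linkages` (warnings are not persisted)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise CohortParseError(f"{path}: linkage file has no rows")
    first = df.iloc[0]
    links = LinkSet(int(first["year1"]), int(first["year2"]), int(first["threshold"]))

    def to_score(row) -> LinkageScore:
        return LinkageScore(
            id1=row["id1"],
            id2=row["id2"],
            code=int(row["code_subscore"]),
            forward=int(row["forward"]),
            backward=int(row["backward"]),
            distance_km=float(row["distance_km"]) if row["distance_km"] else float("nan"),
        )

    queued: dict[tuple[int, int], list[tuple[str, str]]] = {}
    queue_totals: dict[tuple[int, int], int] = {}
    for _, row in df.iterrows():
        status = row["status"]
        if status == "accepted":
            s = to_score(row)
            links.accepted[s.pair] = s
        elif status == "rejected_cross_city":
            s = to_score(row)
            links.rejected_cross_city[s.pair] = s
        elif status == "queued":
            key = (int(row["group_id"]), int(row["side"]))
            queued.setdefault(key, []).append((row["id1"], row["id2"]))
            queue_totals[key] = int(row["total"])
        elif status == "unlinked":
            if row["id1"]:
                links.unlinked_year1.add(row["id1"])
            else:
                links.unlinked_year2.add(row["id2"])
        else:
            raise CohortParseError(f"{path}: unknown status {status!r}")
    for (gid, side), pairs in sorted(queued.items()):
        facility = pairs[0][0] if side == 1 else pairs[0][1]
        links.review_queue.append(
            TieGroup(facility, side, queue_totals[(gid, side)], tuple(pairs))
        )
    return links


def write_similarity_csv(sm, path: str | Path) -> None:
    """Long-format audit export of a similarity matrix."""
    rows = [
        {
            "id1": s.id1,
            "id2": s.id2,
            "code_subscore": s.code,
            "forward": s.forward,
            "backward": s.backward,
            "location_subscore": s.location,
            "total": s.total,
            "distance_km": "" if math.isnan(s.distance_km) else repr(s.distance_km),
        }
        for s in sorted(sm.scores.values(), key=lambda s: (s.id1, s.id2))
    ]
    cols = ["id1", "id2", "code_subscore", "forward", "backward",
            "location_subscore", "total", "distance_km"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_continuity_csv(table, path: str | Path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "year": r.year,
            "role": r.role,
            "continuity_type": r.continuity_type,
            "division_flag": r.division_flag,
            "merge_flag": r.merge_flag,
            "pending_review": r.pending_review,
            "partner_id": r.partner_id or "",
            "total": "" if r.total is None else r.total,
        }
        for r in table.rows
    ]
    cols = ["record_id", "year", "role", "continuity_type", "division_flag",
            "merge_flag", "pending_review", "partner_id", "total"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_gold_csv(path: str | Path) -> list[tuple[str, str]]:
    """Read reference linkages as (id_year1, id_year2) pairs."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("id_year1", "id_year2"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing column {col!r}")
    return [(r.id_year1, r.id_year2) for r in df.itertuples(index=False)]


def write_gold_csv(pairs: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["id_year1", "id_year2"]).to_csv(path, index=False)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    try:
        return RunConfig.from_dict(data)
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
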