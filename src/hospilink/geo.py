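"""Great-circle distances and the forward/backward nearest-neighbor structure.

Location similarity between two annual cohorts is rank-based: what matters
is which year-two site is *nearest* to a year-one site (and vice versa) and
whether that nearest distance is zero, i.e. no relocation. Distances are
haversine great-circle distances; sub-kilometer metric refinements are
irrelevant because only rank order and exact zero enter the score.

Distances at or below ``zero_distance_epsilon_m`` are snapped to exactly
0 km so that geocoding jitter does not turn "same address" into a small
positive relocation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import RunConfig, YearCohort

__all__ = ["haversine_distance", "DistanceMatrix", "distance_matrix", "nearest_sets"]


class EmptyCohortError(ValueError):
    """Raised when an operation requires a non-empty cohort."""


def _check_coord(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValueError(f"coordinate ({lat}, {lon}) out of range")


def haversine_distance(
    a: tuple[float, float], b: tuple[float, float], earth_radius_km: float = 6371.0
) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    _check_coord(*a)
    _check_coord(*b)
    lat1, lon1, lat2, lon2 = map(np.radians, (a[0], a[1], b[0], b[1]))
    h = np.sin((lat2 - lat1) / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(
        (lon2 - lon1) / 2.0
    ) ** 2
    return float(2.0 * earth_radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def _pairwise_haversine_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray, radius_km: float
) -> np.ndarray:
    """|1|x|2| haversine matrix; NaN coordinates propagate to NaN distances."""
    p1 = np.radians(np.column_stack([lat1, lon1]))[:, None, :]
    p2 = np.radians(np.column_stack([lat2, lon2]))[None, :, :]
    dlat = p2[..., 0] - p1[..., 0]
    dlon = p2[..., 1] - p1[..., 1]
    h = np.sin(dlat / 2.0) ** 2 + np.cos(p1[..., 0]) * np.cos(p2[..., 0]) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class DistanceMatrix:
    """Dense distance structure between a year-one and a year-two cohort.

    ``d[i, j]`` is the (epsilon-snapped) distance in km between row record i
    and column record j; NaN where either record has no coordinates. Records
    without coordinates have empty argmin sets — they contribute no location
    evidence.
    """

    row_ids: list[str]
    col_ids: list[str]
    d: np.ndarray  # km, NaN for coordinate-less records
    row_argmin: dict[str, set[str]]
    col_argmin: dict[str, set[str]]
    row_min: dict[str, float]
    col_min: dict[str, float]

    def distance(self, id1: str, id2: str) -> float:
        return float(self.d[self._ri[id1], self._ci[id2]])

    def __post_init__(self) -> None:
        self._ri = {r: i for i, r in enumerate(self.row_ids)}
        self._ci = {c: j for j, c in enumerate(self.col_ids)}


def _argmin_sets(
    d: np.ndarray, row_ids: list[str], col_ids: list[str]
) -> tuple[dict[str, set[str]], dict[str, float]]:
    """Per-row argmin id sets (ties preserved) and minimal distances."""
    argmin: dict[str, set[str]] = {}
    dmin: dict[str, float] = {}
    with np.errstate(invalid="ignore"):
        for i, rid in enumerate(row_ids):
            row = d[i]
            if np.all(np.isnan(row)):
                argmin[rid] = set()
                dmin[rid] = float("nan")
                continue
            m = np.nanmin(row)
            argmin[rid] = {col_ids[j] for j in np.flatnonzero(row == m)}
            dmin[rid] = float(m)
    return argmin, dmin


def distance_matrix(
    cohort1: YearCohort, cohort2: YearCohort, config: RunConfig | None = None
) -> DistanceMatrix:
    """Full |cohort1| x |cohort2| distance matrix with nearest-neighbor sets.

    Raises :class:`EmptyCohortError` if either cohort is empty.
    """
    config = config or RunConfig()
    if len(cohort1) == 0 or len(cohort2) == 0:
        raise EmptyCohortError("distance_matrix requires two non-empty cohorts")

    lat1 = np.array([r.lat if r.has_coord else np.nan for r in cohort1], dtype=float)
    lon1 = np.array([r.lon if r.has_coord else np.nan for r in cohort1], dtype=float)
    lat2 = np.array([r.lat if r.has_coord else np.nan for r in cohort2], dtype=float)
    lon2 = np.array([r.lon if r.has_coord else np.nan for r in cohort2], dtype=float)

    d = _pairwise_haversine_km(lat1, lon1, lat2, lon2, config.earth_radius_km)
    eps_km = config.zero_distance_epsilon_m / 1000.0
    with np.errstate(invalid="ignore"):
        d[d <= eps_km] = 0.0

    row_ids, col_ids = cohort1.ids, cohort2.ids
    row_argmin, row_min = _argmin_sets(d, row_ids, col_ids)
    col_argmin, col_min = _argmin_sets(d.T, col_ids, row_ids)
    return DistanceMatrix(row_ids, col_ids, d, row_argmin, col_argmin, row_min, col_min)


def nearest_sets(
    dm: DistanceMatrix, direction: str = "forward"
) -> dict[str, tuple[set[str], float, bool]]:
    """Map each record to ``(argmin ids, min distance, is_zero)``.

    ``forward`` maps year-one records onto their nearest year-two records,
    ``backward`` the reverse. Ties are preserved as sets; records without
    coordinates map to an empty set with NaN distance.
    """
    if direction == "forward":
        argmin, dmin = dm.row_argmin, dm.row_min
    elif direction == "backward":
        argmin, dmin = dm.col_argmin, dm.col_min
    else:
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    return {
        rid: (set(ids), dmin[rid], bool(ids) and dmin[rid] == 0.0)
        for rid, ids in argmin.items()
    }
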