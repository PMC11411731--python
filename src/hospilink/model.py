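"""Core data model: facility records, annual cohorts, and run configuration.

A *facility record* is one hospital site observed in one reporting year. Two
key variables drive longitudinal linkage: the administrative identification
code — an institution identification code (IIC) optionally refined by a site
code (SC) — and the geographic location of the site. Everything else
(name, ownership, beds, ...) is descriptive and used only for reporting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping

__all__ = [
    "FacilityRecord",
    "YearCohort",
    "RunConfig",
    "normalize_municipality",
    "normalize_sc",
]

_PUNCT_WS = re.compile(r"[\s\.\,\-\/\(\)]+")


def normalize_municipality(name: str | None) -> str | None:
    """Case-fold and strip whitespace/punctuation so that e.g. 'Frankfurt a.M.'
    and 'frankfurt a m' compare equal. Returns ``None`` for empty input."""
    if name is None:
        return None
    folded = _PUNCT_WS.sub(" ", name.casefold()).strip()
    return folded or None


def normalize_sc(sc: str | None) -> str | None:
    """Canonical site-code form: strip whitespace and leading zeros.

    Site codes switched from short 2-digit to 9-digit strings nationally;
    '01' and '1' denote the same site, so leading zeros are not significant.
    """
    if sc is None:
        return None
    s = str(sc).strip()
    if not s:
        return None
    stripped = s.lstrip("0")
    return stripped if stripped else "0"


@dataclass(frozen=True)
class FacilityRecord:
    """One hospital site in one year.

    ``lat``/``lon`` are WGS84 decimal degrees; both may be ``None`` when the
    site could not be geocoded (such records can still link by code but
    contribute no location evidence). ``sc`` may be ``None`` when the source
    year reports no site code.
    """

    record_id: str
    year: int
    iic: str
    sc: str | None = None
    lat: float | None = None
    lon: float | None = None
    municipality: str | None = None
    attributes: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.iic or not str(self.iic).strip():
            raise ValueError(f"record {self.record_id!r}: IIC must be non-empty")
        if (self.lat is None) != (self.lon is None):
            raise ValueError(
                f"record {self.record_id!r}: latitude and longitude must be "
                "both present or both absent"
            )
        if self.lat is not None:
            if not -90.0 <= self.lat <= 90.0:
                raise ValueError(
                    f"record {self.record_id!r}: latitude {self.lat} outside [-90, 90]"
                )
            if not -180.0 <= self.lon <= 180.0:
                raise ValueError(
                    f"record {self.record_id!r}: longitude {self.lon} outside [-180, 180]"
                )

    @property
    def has_coord(self) -> bool:
        return self.lat is not None

    @property
    def sc_norm(self) -> str | None:
        return normalize_sc(self.sc)

    @property
    def municipality_norm(self) -> str | None:
        return normalize_municipality(self.municipality)


@dataclass
class YearCohort:
    """All facility records of one reporting year, indexed by record id."""

    year: int
    records: list[FacilityRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.year != self.year:
                raise ValueError(
                    f"record {rec.record_id!r} has year {rec.year}, cohort year {self.year}"
                )
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id {rec.record_id!r} in cohort {self.year}")
            seen.add(rec.record_id)
        self._by_id = {rec.record_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FacilityRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> FacilityRecord:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [rec.record_id for rec in self.records]


SC_MODES = ("full", "iic_only")


@dataclass
class RunConfig:
    """Linkage run parameters.

    sc_mode
        ``"full"`` compares IIC and SC; ``"iic_only"`` ignores SC, the regime
        needed around the national site-code renumbering when SC values are
        not comparable across years.
    zero_distance_epsilon_m
        Distances at or below this many meters count as "no relocation"
        (absorbs geocoding jitter). Default 10 m.
    tolerance_threshold
        Minimum total score (1..8) for an acceptable linkage. Default 1:
        any positive similarity is admissible, matching the score taxonomy
        that accepts linkages down to a total of 1.
    same_municipality_required
        Whether accepted linkages crossing a city/town are discarded.
    """

    sc_mode: str = "full"
    zero_distance_epsilon_m: float = 10.0
    tolerance_threshold: int = 1
    same_municipality_required: bool = True
    earth_radius_km: float = 6371.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sc_mode not in SC_MODES:
            raise ValueError(f"sc_mode must be one of {SC_MODES}, got {self.sc_mode!r}")
        if not 1 <= int(self.tolerance_threshold) <= 8:
            raise ValueError(f"tolerance_threshold must be in [1, 8], got {self.tolerance_threshold}")
        if self.zero_distance_epsilon_m < 0:
            raise ValueError("zero_distance_epsilon_m must be >= 0")
        if self.earth_radius_km <= 0:
            raise ValueError("earth_radius_km must be positive")

    def to_dict(self) -> dict[str, Any]:
        return {
            "sc_mode": self.sc_mode,
            "zero_distance_epsilon_m": self.zero_distance_epsilon_m,
            "tolerance_threshold": self.tolerance_threshold,
            "same_municipality_required": self.same_municipality_required,
            "earth_radius_km": self.earth_radius_km,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)
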