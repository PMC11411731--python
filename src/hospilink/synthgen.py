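"""Synthetic multi-year hospital-site panels with ground-truth linkage.

The generator emulates the event structure of an annual national hospital
registry: the overwhelming majority of sites persist unchanged from one
year to the next, while small fractions change their site code (SC), change
their institution code (IIC), relocate within their municipality, close,
open, split into two sites, or merge. Default per-transition rates follow
the magnitudes observed in the German registry (~93–98% constant, ~1–6%
SC-only change, ~0.7–1.1% IIC change, ~0.4–0.8% relocation, ~0.1–1.2%
openings/closures).

Spatially, municipalities are Gaussian clusters of sites on a lat/lon patch
of Germany-like extent (47–55 N, 6–15 E). Only rank-order distances and
exact coordinate identity matter to the linkage method, so no further
geographic realism is attempted.

Every cohort comes with a gold-standard matching to the next year's cohort
and a full event log; a facility has a gold pair across a transition iff
its event is not an opening or a closure. Record ids are re-issued every
year, so recovering the gold matching is a genuine linkage problem.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import GoldStandard
from .model import FacilityRecord, YearCohort

__all__ = ["SimulationConfig", "SyntheticPanel", "generate_panel", "perturb_addresses"]

_LAT_RANGE = (47.0, 55.0)
_LON_RANGE = (6.0, 15.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel.

    Event rates are per facility per year-to-year transition; the constant
    rate is the remainder ``1 - sum(other rates)``. ``p_open`` is the
    expected number of new openings as a fraction of the current cohort
    size. ``coordinate_jitter_m`` adds isotropic geocoding noise of that
    magnitude to every reported coordinate (0 = exact addresses).
    ``sc_regime_switch_year``: from that calendar year on, all site codes
    are re-issued in a long 9-digit format, reproducing a national SC
    renumbering (an SC change for every facility at once).
    """

    n_facilities: int = 1150
    n_years: int = 5
    first_year: int = 2016
    n_municipalities: int = 80
    municipality_sigma_deg: float = 0.02
    p_sc_change: float = 0.03
    p_iic_change: float = 0.009
    p_relocate: float = 0.006
    p_close: float = 0.005
    p_open: float = 0.005
    p_split: float = 0.001
    p_merge: float = 0.001
    relocation_sigma_deg: float = 0.01
    coordinate_jitter_m: float = 0.0
    sc_regime_switch_year: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        rates = self.event_rates()
        for name, p in rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rate {name} = {p} outside [0, 1]")
        if sum(rates.values()) > 1.0 + 1e-12:
            raise ValueError("per-facility event rates sum to more than 1")
        if self.n_facilities < 0 or self.n_years < 1:
            raise ValueError("need n_facilities >= 0 and n_years >= 1")
        if self.n_municipalities < 1:
            raise ValueError("need at least one municipality")

    def event_rates(self) -> dict[str, float]:
        return {
            "sc_change": self.p_sc_change,
            "iic_change": self.p_iic_change,
            "relocate": self.p_relocate,
            "close": self.p_close,
            "split": self.p_split,
            "merge": self.p_merge,
        }


@dataclass(frozen=True)
class Event:
    year_from: int
    year_to: int
    kind: str
    record_id_from: str | None
    record_id_to: str | None


@dataclass
class SyntheticPanel:
    """Cohorts per year, gold matchings per adjacent pair, and event log."""

    cohorts: list[YearCohort]
    golds: list[GoldStandard]
    events: list[Event] = field(default_factory=list)

    @property
    def years(self) -> list[int]:
        return [c.year for c in self.cohorts]


@dataclass
class _Facility:
    """Mutable latent state of one hospital site across years."""

    key: int  # latent identity, never exposed to the linker
    iic: str
    sc: str
    lat: float
    lon: float
    municipality: str
    attrs: dict


class _CodeFactory:
    """Issues unique IIC and SC strings deterministically."""

    def __init__(self) -> None:
        self._iic = 0
        self._sc_short = 0
        self._sc_long = 0

    def iic(self) -> str:
        self._iic += 1
        return f"26{self._iic:07d}"

    def sc(self, long_format: bool) -> str:
        if long_format:
            self._sc_long += 1
            return f"77{self._sc_long:07d}"
        self._sc_short += 1
        return f"{(self._sc_short - 1) % 99 + 1:02d}"


def _jitter(rng: np.random.Generator, lat: float, lon: float, meters: float) -> tuple[float, float]:
    if meters <= 0:
        return lat, lon
    deg = meters / 111_000.0  # ~1 deg latitude in meters
    dlat, dlon = rng.normal(0.0, deg, size=2)
    return lat + dlat, lon + dlon


def generate_panel(config: SimulationConfig) -> SyntheticPanel:
    """Simulate the panel; deterministic given the config (incl. its seed)."""
    rng = np.random.default_rng(config.seed)
    codes = _CodeFactory()

    mun_lat = rng.uniform(*_LAT_RANGE, size=config.n_municipalities)
    mun_lon = rng.uniform(*_LON_RANGE, size=config.n_municipalities)
    mun_names = [f"Stadt {i + 1:03d}" for i in range(config.n_municipalities)]
    ownerships = ("public", "non-profit", "private")

    next_key = 0

    def long_sc(year: int) -> bool:
        return (
            config.sc_regime_switch_year is not None
            and year >= config.sc_regime_switch_year
        )

    def new_facility(year: int) -> _Facility:
        nonlocal next_key
        m = int(rng.integers(config.n_municipalities))
        lat = float(mun_lat[m] + rng.normal(0.0, config.municipality_sigma_deg))
        lon = float(mun_lon[m] + rng.normal(0.0, config.municipality_sigma_deg))
        fac = _Facility(
            key=next_key,
            iic=codes.iic(),
            sc=codes.sc(long_sc(year)),
            lat=float(np.clip(lat, *_LAT_RANGE)),
            lon=float(np.clip(lon, *_LON_RANGE)),
            municipality=mun_names[m],
            attrs={
                "name": f"Klinik {next_key + 1}",
                "ownership": str(rng.choice(ownerships)),
                "beds": int(rng.integers(50, 1500)),
            },
        )
        next_key += 1
        return fac

    def relocate(fac: _Facility) -> None:
        m = mun_names.index(fac.municipality)
        while True:
            lat = float(mun_lat[m] + rng.normal(0.0, config.relocation_sigma_deg))
            lon = float(mun_lon[m] + rng.normal(0.0, config.relocation_sigma_deg))
            if (lat, lon) != (fac.lat, fac.lon):
                break
        fac.lat = float(np.clip(lat, *_LAT_RANGE))
        fac.lon = float(np.clip(lon, *_LON_RANGE))

    def make_cohort(year: int, facilities: list[_Facility]) -> tuple[YearCohort, dict[int, str]]:
        ids: dict[int, str] = {}
        records = []
        for k, fac in enumerate(facilities):
            rid = f"Y{year}-{k + 1:05d}"
            ids[fac.key] = rid
            lat, lon = _jitter(rng, fac.lat, fac.lon, config.coordinate_jitter_m)
            records.append(
                FacilityRecord(
                    record_id=rid,
                    year=year,
                    iic=fac.iic,
                    sc=fac.sc,
                    lat=float(np.clip(lat, -90.0, 90.0)),
                    lon=float(np.clip(lon, -180.0, 180.0)),
                    municipality=fac.municipality,
                    attributes=dict(fac.attrs),
                )
            )
        return YearCohort(year=year, records=records), ids

    facilities = [new_facility(config.first_year) for _ in range(config.n_facilities)]
    cohorts: list[YearCohort] = []
    golds: list[GoldStandard] = []
    events: list[Event] = []

    cohort, id_of = make_cohort(config.first_year, facilities)
    cohorts.append(cohort)

    rates = config.event_rates()
    kinds = list(rates)
    probs = np.array([rates[k] for k in kinds] + [1.0 - sum(rates.values())])
    kinds.append("constant")

    for step in range(1, config.n_years):
        y1 = config.first_year + step - 1
        y2 = config.first_year + step
        prev_ids = id_of
        regime_flip = long_sc(y2) and not long_sc(y1)

        survivors: list[_Facility] = []
        gold_keys: list[int] = []
        drawn = rng.choice(len(kinds), size=len(facilities), p=probs)
        openings: list[_Facility] = []
        for fac, ki in zip(facilities, drawn):
            kind = kinds[ki]
            if kind == "close":
                events.append(Event(y1, y2, "close", prev_ids[fac.key], None))
                continue
            if kind == "merge":
                # absorbed into another institution: the site disappears
                events.append(Event(y1, y2, "merge_closed", prev_ids[fac.key], None))
                continue
            if kind == "sc_change":
                fac.sc = codes.sc(long_sc(y2))
            elif kind == "iic_change":
                fac.iic = codes.iic()
            elif kind == "relocate":
                relocate(fac)
            elif kind == "split":
                sibling = new_facility(y2)
                sibling.municipality = fac.municipality
                m = mun_names.index(fac.municipality)
                sibling.lat = float(
                    np.clip(mun_lat[m] + rng.normal(0.0, config.municipality_sigma_deg), *_LAT_RANGE)
                )
                sibling.lon = float(
                    np.clip(mun_lon[m] + rng.normal(0.0, config.municipality_sigma_deg), *_LON_RANGE)
                )
                openings.append(sibling)
                events.append(Event(y1, y2, "split_new_site", None, None))
            if kind != "constant":
                events.append(Event(y1, y2, kind, prev_ids[fac.key], None))
            survivors.append(fac)
            gold_keys.append(fac.key)

        if regime_flip:
            for fac in survivors:
                fac.sc = codes.sc(True)
            events.append(Event(y1, y2, "sc_regime_switch", None, None))

        n_open = int(rng.binomial(max(len(survivors), 1), config.p_open))
        for _ in range(n_open):
            fac = new_facility(y2)
            openings.append(fac)
        for fac in openings:
            events.append(Event(y1, y2, "open", None, None))
        facilities = survivors + openings

        cohort, id_of = make_cohort(y2, facilities)
        cohorts.append(cohort)
        pairs = [(prev_ids[k], id_of[k]) for k in gold_keys]
        golds.append(GoldStandard(pairs=pairs))

    return SyntheticPanel(cohorts=cohorts, golds=golds, events=events)


def perturb_addresses(
    panel: SyntheticPanel, error_rate: float, seed: int = 0
) -> SyntheticPanel:
    """Corrupt the coordinates of a sampled fraction of facilities in one
    randomly chosen year each, emulating single-year address input errors.

    The shift is 200–2000 m in a random direction — large enough to defeat
    zero-distance snapping, small enough to stay within the municipality.
    Corrupted records are appended to the event log as ``address_error``.
    Returns a new panel; the input is not modified.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(panel)

    # longitudinal chains from the gold matchings: each chain is one facility
    succ: dict[tuple[int, str], tuple[int, str]] = {}
    has_pred: set[tuple[int, str]] = set()
    for gold, c1, c2 in zip(out.golds, out.cohorts, out.cohorts[1:]):
        for id1, id2 in gold.pairs:
            succ[(c1.year, id1)] = (c2.year, id2)
            has_pred.add((c2.year, id2))
    chains: list[list[tuple[int, str]]] = []
    for cohort in out.cohorts:
        for rec in cohort:
            node = (cohort.year, rec.record_id)
            if node in has_pred:
                continue
            chain = [node]
            while chain[-1] in succ:
                chain.append(succ[chain[-1]])
            chains.append(chain)

    by_year = {c.year: c for c in out.cohorts}
    for chain in chains:
        if rng.random() >= error_rate:
            continue
        year, rid = chain[int(rng.integers(len(chain)))]
        cohort = by_year[year]
        idx = cohort.ids.index(rid)
        rec = cohort.records[idx]
        if not rec.has_coord:
            continue
        dist_deg = rng.uniform(200.0, 2000.0) / 111_000.0
        angle = rng.uniform(0.0, 2.0 * np.pi)
        new = replace(
            rec,
            lat=float(np.clip(rec.lat + dist_deg * np.sin(angle), -90.0, 90.0)),
            lon=float(np.clip(rec.lon + dist_deg * np.cos(angle), -180.0, 180.0)),
        )
        cohort.records[idx] = new
        cohort._by_id[rid] = new
        out.events.append(Event(year, year, "address_error", rid, None))
    return out
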