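"""Survey observations, oiling categories, and Table-1-style tallying.

The winter 2010-11 Deepwater Horizon waterbird assessment recorded individual
sightings of American white pelicans (AMWP), common loons (COLO), and northern
gannets (NOGA) along the northern Gulf of Mexico.  A bird could only be scored
for external oiling ("assessed") when more than 50% of its body surface was
clearly visible; assessed birds were placed in one of five ordinal categories
by the fraction of body surface visibly oiled.

This module holds the observation record type, CSV IO, and the count/rate
arithmetic that produces the published exposure summaries: per-species tallies,
oiling (exposure) rates over assessed birds, category shares among oiled birds,
per-state breakdowns, and the photograph-review adjustment that upgraded two
gannets from unoiled to trace.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import functools
import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Species",
    "State",
    "OilingCategory",
    "OILED_CATEGORIES",
    "ObservationRecord",
    "SurveyTally",
    "StateRates",
    "NoAssessedBirdsError",
    "NoOiledBirdsError",
    "DEFAULT_WINDOW",
    "read_observations",
    "write_observations",
    "tally",
    "exposure_rate",
    "category_shares",
    "state_breakdown",
    "apply_photo_review",
]


class Species(str, enum.Enum):
    """Target species, by their standard four-letter field codes."""

    AMWP = "AMWP"  # American white pelican (Pelecanus erythrorhynchos)
    COLO = "COLO"  # common loon (Gavia immer)
    NOGA = "NOGA"  # northern gannet (Morus bassanus)


class State(str, enum.Enum):
    """US Gulf states covered by the nearshore surveys."""

    LA = "LA"
    MS = "MS"
    AL = "AL"
    FL = "FL"


@functools.total_ordering
class OilingCategory(enum.Enum):
    """Ordinal oiling severity by percent of body surface visibly oiled.

    Bands are contiguous and half-open, ``(lo, hi]`` percent: none is exactly
    0%, trace (0, 5], light (5, 20], moderate (20, 40], heavy (40, 100].
    The published labels leave small gaps (trace "<5%", light "6-20%"); those
    are printing artifacts and the seams here assign every surface fraction to
    exactly one category.
    """

    NONE = 0
    TRACE = 1
    LIGHT = 2
    MODERATE = 3
    HEAVY = 4

    @property
    def surface_band(self) -> tuple[float, float]:
        """(lo, hi] band of percent body surface oiled; none is (0, 0)."""
        return _SURFACE_BANDS[self]

    @property
    def surface_lo(self) -> float:
        return self.surface_band[0]

    @property
    def surface_hi(self) -> float:
        return self.surface_band[1]

    def __lt__(self, other: "OilingCategory") -> bool:
        if not isinstance(other, OilingCategory):
            return NotImplemented
        return self.value < other.value

    @classmethod
    def parse(cls, text: str) -> "OilingCategory":
        """Parse a category label case-insensitively."""
        try:
            return cls[text.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown oiling category {text!r}") from None

    @classmethod
    def from_surface(cls, percent: float) -> "OilingCategory":
        """Map a percent-of-body-surface value onto its category."""
        if not 0 <= percent <= 100:
            raise ValueError(f"surface percent out of [0, 100]: {percent}")
        if percent == 0:
            return cls.NONE
        for cat in (cls.TRACE, cls.LIGHT, cls.MODERATE, cls.HEAVY):
            lo, hi = cat.surface_band
            if lo < percent <= hi:
                return cat
        raise AssertionError("unreachable: bands cover (0, 100]")


_SURFACE_BANDS: dict[OilingCategory, tuple[float, float]] = {
    OilingCategory.NONE: (0.0, 0.0),
    OilingCategory.TRACE: (0.0, 5.0),
    OilingCategory.LIGHT: (5.0, 20.0),
    OilingCategory.MODERATE: (20.0, 40.0),
    OilingCategory.HEAVY: (40.0, 100.0),
}

#: The visibly-oiled categories, in severity order.
OILED_CATEGORIES: tuple[OilingCategory, ...] = (
    OilingCategory.TRACE,
    OilingCategory.LIGHT,
    OilingCategory.MODERATE,
    OilingCategory.HEAVY,
)

#: Default survey window (the winter assessment field season).
DEFAULT_WINDOW: tuple[datetime.date, datetime.date] = (
    datetime.date(2011, 1, 1),
    datetime.date(2011, 4, 30),
)


class NoAssessedBirdsError(ValueError):
    """Raised when a rate needs assessed birds and the tally has none."""


class NoOiledBirdsError(ValueError):
    """Raised when category shares are requested with zero oiled birds."""


@dataclasses.dataclass(frozen=True)
class ObservationRecord:
    """One bird sighting.

    ``assessed`` encodes the >50%-body-surface-visible eligibility rule:
    only assessed birds carry an oiling category.  An unassessed bird has
    ``category is None`` - absence of evidence, not an implicit "none".
    ``record_id`` is the 0-based data-row index within the source file and
    stays stable under filtering.
    """

    record_id: int
    species: Species
    state: State
    grid_id: str
    date: datetime.date
    assessed: bool
    category: OilingCategory | None = None
    lat: float | None = None
    lon: float | None = None
    distance_m: float | None = None
    photo_reviewed: bool = False

    def __post_init__(self) -> None:
        if self.assessed and self.category is None:
            raise ValueError(
                f"record {self.record_id}: assessed bird must carry a category"
            )
        if not self.assessed and self.category is not None:
            raise ValueError(
                f"record {self.record_id}: unassessed bird cannot carry a category"
            )

    @property
    def oiled(self) -> bool:
        """True iff assessed and in any visibly-oiled category."""
        return self.category is not None and self.category != OilingCategory.NONE


@dataclasses.dataclass(frozen=True)
class SurveyTally:
    """Per-species counts: observed, assessed, and assessed-oiled by category.

    ``n_by_category`` covers the oiled categories only (trace..heavy);
    unoiled assessed birds are ``n_assessed - n_oiled``.  ``by_state`` holds
    the same counts restricted to each state with at least one bird.
    """

    species: Species
    n_observed: int
    n_assessed: int
    n_by_category: Mapping[OilingCategory, int]
    by_state: Mapping[State, "SurveyTally"] | None = None

    def __post_init__(self) -> None:
        counts = dict(self.n_by_category)
        for cat in OILED_CATEGORIES:
            counts.setdefault(cat, 0)
        bad = set(counts) - set(OILED_CATEGORIES)
        if bad:
            raise ValueError(f"non-oiled categories in tally: {sorted(c.name for c in bad)}")
        object.__setattr__(self, "n_by_category", counts)
        for name, n in (("n_observed", self.n_observed), ("n_assessed", self.n_assessed)):
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {n!r}")
        if any(not isinstance(v, int) or v < 0 for v in counts.values()):
            raise ValueError("category counts must be non-negative integers")
        if self.n_assessed > self.n_observed:
            raise ValueError(
                f"n_assessed ({self.n_assessed}) exceeds n_observed ({self.n_observed})"
            )
        if self.n_oiled > self.n_assessed:
            raise ValueError(
                f"oiled count ({self.n_oiled}) exceeds n_assessed ({self.n_assessed})"
            )
        if self.by_state is not None:
            if sum(t.n_observed for t in self.by_state.values()) != self.n_observed:
                raise ValueError("per-state observed counts do not sum to the total")

    @property
    def n_oiled(self) -> int:
        """Number of assessed birds in any visibly-oiled category."""
        return sum(self.n_by_category.values())

    def to_dict(self) -> dict:
        d = {
            "species": self.species.value,
            "n_observed": self.n_observed,
            "n_assessed": self.n_assessed,
            "n_by_category": {c.name.lower(): n for c, n in self.n_by_category.items()},
        }
        if self.by_state is not None:
            d["by_state"] = {s.value: t.to_dict() for s, t in self.by_state.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurveyTally":
        by_state = None
        if d.get("by_state"):
            by_state = {State(s): cls.from_dict(t) for s, t in d["by_state"].items()}
        return cls(
            species=Species(d["species"]),
            n_observed=int(d["n_observed"]),
            n_assessed=int(d["n_assessed"]),
            n_by_category={
                OilingCategory.parse(k): int(v) for k, v in d["n_by_category"].items()
            },
            by_state=by_state,
        )


CSV_COLUMNS = [
    "species",
    "state",
    "grid_id",
    "date",
    "lat",
    "lon",
    "distance_m",
    "assessed",
    "category",
    "photo_reviewed",
]

_BOOL = {"true": True, "false": False}


def _parse_bool(text: str, row: int, field: str) -> bool:
    try:
        return _BOOL[text.strip().lower()]
    except KeyError:
        raise ValueError(f"row {row}: bad boolean for {field}: {text!r}") from None


def read_observations(
    path: str | Path,
    window: tuple[datetime.date, datetime.date] = DEFAULT_WINDOW,
) -> list[ObservationRecord]:
    """Read observation records from the standard CSV.

    Rows with a date outside ``window`` are dropped with a logged warning
    (they are legitimate observations, just out of season); malformed rows
    are hard errors naming the 0-based data-row number.  Record ids are the
    data-row index, so they remain stable under the window filter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"observations file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != CSV_COLUMNS:
        raise ValueError(
            f"unexpected CSV header {list(frame.columns)}; expected {CSV_COLUMNS}"
        )
    records: list[ObservationRecord] = []
    n_rejected = 0
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            species = Species(row.species.strip().upper())
            state = State(row.state.strip().upper())
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
        try:
            date = datetime.date.fromisoformat(row.date.strip())
        except ValueError:
            raise ValueError(f"row {i}: bad ISO date {row.date!r}") from None
        assessed = _parse_bool(row.assessed, i, "assessed")
        category = None
        if row.category.strip():
            category = OilingCategory.parse(row.category)
        if assessed and category is None:
            raise ValueError(f"row {i}: assessed=true but no oiling category")
        if not assessed and category is not None:
            raise ValueError(f"row {i}: category given for unassessed bird")
        if not (window[0] <= date <= window[1]):
            n_rejected += 1
            logger.warning("row %d: date %s outside survey window, skipped", i, date)
            continue
        records.append(
            ObservationRecord(
                record_id=i,
                species=species,
                state=state,
                grid_id=row.grid_id.strip(),
                date=date,
                assessed=assessed,
                category=category,
                lat=float(row.lat) if row.lat.strip() else None,
                lon=float(row.lon) if row.lon.strip() else None,
                distance_m=float(row.distance_m) if row.distance_m.strip() else None,
                photo_reviewed=_parse_bool(row.photo_reviewed, i, "photo_reviewed"),
            )
        )
    if n_rejected:
        logger.warning("%d of %d rows outside the survey window", n_rejected, len(frame))
    return records


def _fmt_opt(value: float | None) -> str:
    return "" if value is None else format(value, "g")


def write_observations(records: Iterable[ObservationRecord], path: str | Path) -> None:
    """Write records to the standard observations CSV (UTF-8, header)."""
    rows = [
        {
            "species": r.species.value,
            "state": r.state.value,
            "grid_id": r.grid_id,
            "date": r.date.isoformat(),
            "lat": _fmt_opt(r.lat),
            "lon": _fmt_opt(r.lon),
            "distance_m": _fmt_opt(r.distance_m),
            "assessed": str(r.assessed).lower(),
            "category": r.category.name.lower() if r.category is not None else "",
            "photo_reviewed": str(r.photo_reviewed).lower(),
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    frame.to_csv(path, index=False)


def _tally_counts(records: Sequence[ObservationRecord], species: Species) -> tuple:
    n_observed = len(records)
    n_assessed = sum(r.assessed for r in records)
    counts = Counter(
        r.category for r in records if r.category is not None and r.oiled
    )
    return n_observed, n_assessed, {c: counts.get(c, 0) for c in OILED_CATEGORIES}


def tally(records: Iterable[ObservationRecord], species: Species) -> SurveyTally:
    """Tally observed/assessed/oiled-by-category counts for one species.

    Records of other species are ignored; an empty input yields an all-zero
    tally.  Per-state sub-tallies are included for every state with at least
    one bird of the species.
    """
    mine = [r for r in records if r.species == species]
    n_obs, n_ass, by_cat = _tally_counts(mine, species)
    by_state: dict[State, SurveyTally] = {}
    for state in State:
        here = [r for r in mine if r.state == state]
        if not here:
            continue
        s_obs, s_ass, s_cat = _tally_counts(here, species)
        by_state[state] = SurveyTally(species, s_obs, s_ass, s_cat)
    return SurveyTally(species, n_obs, n_ass, by_cat, by_state=by_state)


def exposure_rate(t: SurveyTally) -> float:
    """Fraction of assessed birds showing any visible oiling."""
    if t.n_assessed == 0:
        raise NoAssessedBirdsError(f"no assessed birds for {t.species.value}")
    return t.n_oiled / t.n_assessed


def category_shares(t: SurveyTally) -> dict[OilingCategory, float]:
    """Share of each oiled category among visibly-oiled birds; sums to 1."""
    if t.n_oiled == 0:
        raise NoOiledBirdsError(f"no oiled birds for {t.species.value}")
    return {c: t.n_by_category[c] / t.n_oiled for c in OILED_CATEGORIES}


class StateRates(NamedTuple):
    """Per-state counts and oiling rate (oiled / assessed in that state)."""

    n_observed: int
    n_assessed: int
    n_oiled: int
    rate: float | None


def state_breakdown(
    records: Iterable[ObservationRecord], species: Species
) -> dict[State, StateRates]:
    """Per-state oiling summary for one species.

    The rate divides oiled birds by the state's assessed count - the only
    denominator the published per-state percentages are consistent with
    (per-state listed counts sum to the species' assessed total).  States
    with no birds are omitted; a state with birds but none assessed gets
    ``rate=None``.
    """
    t = tally(records, species)
    out: dict[State, StateRates] = {}
    for state, st in (t.by_state or {}).items():
        rate = st.n_oiled / st.n_assessed if st.n_assessed else None
        out[state] = StateRates(st.n_observed, st.n_assessed, st.n_oiled, rate)
    return out


def apply_photo_review(
    records: Sequence[ObservationRecord],
    updates: Iterable[tuple[int, OilingCategory]],
) -> list[ObservationRecord]:
    """Apply post-hoc photograph-review category changes.

    Each update is ``(record_id, new_category)`` and must target an assessed
    record; touched records get ``photo_reviewed=True``.  Returns an updated
    copy - the input list is never modified.
    """
    by_id = {r.record_id: i for i, r in enumerate(records)}
    out = list(records)
    for rec_id, new_cat in updates:
        if rec_id not in by_id:
            raise KeyError(f"no record with id {rec_id}")
        idx = by_id[rec_id]
        rec = out[idx]
        if not rec.assessed:
            raise ValueError(f"record {rec_id} was not assessed; cannot re-categorize")
        out[idx] = dataclasses.replace(rec, category=new_cat, photo_reviewed=True)
    return out
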