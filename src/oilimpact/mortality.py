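"""Expert-panel mortality ranges for externally oiled birds.

The Deepwater Horizon Trustees' avian expert panel expressed the probability
that a visibly oiled bird dies as a range per species and oiling category
rather than a point estimate; the simulation treats each range as a uniform
distribution (epistemic uncertainty about the category's true mortality rate).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .survey import OILED_CATEGORIES, OilingCategory, Species

__all__ = [
    "MortalityRange",
    "MortalityTable",
    "default_mortality_table",
    "midpoint",
    "sample_mortality",
]

#: Categories every species must have a range for (heavy is optional in
#: inputs; the built-in table supplies it).
REQUIRED_CATEGORIES = (
    OilingCategory.TRACE,
    OilingCategory.LIGHT,
    OilingCategory.MODERATE,
)


@dataclasses.dataclass(frozen=True, order=True)
class MortalityRange:
    """A [low, high] mortality-probability interval, as fractions."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.high <= 1.0:
            raise ValueError(f"invalid mortality range [{self.low}, {self.high}]")

    @property
    def midpoint(self) -> float:
        return (self.low + self.high) / 2.0


def midpoint(r: MortalityRange) -> float:
    """Arithmetic midpoint of a mortality range (the analytic expectation
    of a uniform draw from it)."""
    return r.midpoint


def sample_mortality(r: MortalityRange, rng: np.random.Generator) -> float:
    """One uniform draw from the range; degenerate ranges return the point."""
    if r.low == r.high:
        return r.low
    return float(rng.uniform(r.low, r.high))


@dataclasses.dataclass(frozen=True)
class MortalityTable:
    """(species, oiling category) -> MortalityRange.

    Invariant: within a species, both range ends are non-decreasing with
    category severity - more oil is never less lethal.
    """

    ranges: Mapping[tuple[Species, OilingCategory], MortalityRange]

    def __post_init__(self) -> None:
        ranges = dict(self.ranges)
        object.__setattr__(self, "ranges", ranges)
        for sp in {s for s, _ in ranges}:
            missing = [c.name for c in REQUIRED_CATEGORIES if (sp, c) not in ranges]
            if missing:
                raise ValueError(f"{sp.value}: missing ranges for {missing}")
            prev: MortalityRange | None = None
            for cat in OILED_CATEGORIES:
                r = ranges.get((sp, cat))
                if r is None:
                    continue
                if prev is not None and (r.low < prev.low or r.high < prev.high):
                    raise ValueError(
                        f"{sp.value}: mortality not monotone at {cat.name.lower()}"
                    )
                prev = r

    def __getitem__(self, key: tuple[Species, OilingCategory]) -> MortalityRange:
        sp, cat = key
        try:
            return self.ranges[key]
        except KeyError:
            raise KeyError(
                f"no mortality range for ({sp.value}, {cat.name.lower()})"
            ) from None

    def __contains__(self, key: tuple[Species, OilingCategory]) -> bool:
        return key in self.ranges

    def __iter__(self) -> Iterator[tuple[Species, OilingCategory]]:
        return iter(self.ranges)

    def species(self) -> set[Species]:
        return {s for s, _ in self.ranges}

    def to_dict(self) -> dict:
        """Percent-valued nested dict, the JSON interchange form."""
        out: dict[str, dict[str, list[float]]] = {}
        for (sp, cat), r in self.ranges.items():
            out.setdefault(sp.value, {})[cat.name.lower()] = [
                r.low * 100.0,
                r.high * 100.0,
            ]
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "MortalityTable":
        """Load from the percent-valued nested dict; values are divided by 100."""
        ranges = {}
        for sp_name, cats in d.items():
            sp = Species(sp_name.strip().upper())
            for cat_name, (lo, hi) in cats.items():
                cat = OilingCategory.parse(cat_name)
                ranges[(sp, cat)] = MortalityRange(lo / 100.0, hi / 100.0)
        return cls(ranges)

    @classmethod
    def from_json(cls, path: str | Path) -> "MortalityTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


# Panel ranges, as fractions: species -> (trace, light, moderate).
_PANEL = {
    Species.AMWP: ((0.00, 0.30), (0.15, 0.70), (0.40, 1.00)),
    Species.COLO: ((0.00, 0.60), (0.80, 0.90), (0.90, 1.00)),
    Species.NOGA: ((0.00, 0.40), (0.30, 0.80), (0.70, 1.00)),
}

# The panel's per-species heavy ranges were not itemized; heavily oiled birds
# were judged 95-100% likely to die, for every species.  No heavily oiled bird
# occurred in the survey data.
_HEAVY = (0.95, 1.00)


def default_mortality_table() -> MortalityTable:
    """The Trustee expert panel's mortality ranges for the three species."""
    ranges: dict[tuple[Species, OilingCategory], MortalityRange] = {}
    for sp, (trace, light, moderate) in _PANEL.items():
        ranges[(sp, OilingCategory.TRACE)] = MortalityRange(*trace)
        ranges[(sp, OilingCategory.LIGHT)] = MortalityRange(*light)
        ranges[(sp, OilingCategory.MODERATE)] = MortalityRange(*moderate)
        ranges[(sp, OilingCategory.HEAVY)] = MortalityRange(*_HEAVY)
    return MortalityTable(ranges)
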