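"""Core domain types for protected-area mosaic analyses.

The analysis compares species composition between adjacent areas under
three management regimes: Strictly Protected areas (SPA, IUCN I-II, no
extraction), Restricted areas (RA, IUCN III-VI, limited extraction) and
Non-Protected areas (NPA). Everything downstream consumes three objects:
a binary survey-by-species incidence matrix, georeferenced survey
metadata, and per-species IUCN red-list status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROTECTION_LEVELS",
    "PROTECTION_RANK",
    "IUCN_CODES",
    "ValidationError",
    "Survey",
    "SpeciesInfo",
    "OccurrenceMatrix",
    "RegionSpec",
    "ComparisonPair",
]

PROTECTION_LEVELS = ("SPA", "RA", "NPA")
#: Ordering of protection strictness; higher rank = stricter protection.
PROTECTION_RANK = {"SPA": 2, "RA": 1, "NPA": 0}

IUCN_CODES = frozenset({"CR", "EN", "VU", "NT", "LC", "DD"})


class ValidationError(ValueError):
    """Raised when an input table or domain object violates its contract."""


@dataclass
class Survey:
    """A single georeferenced survey (transect / plot / point count).

    ``pa_id`` identifies the protected area the survey falls in and is
    required for SPA and RA surveys; NPA surveys carry no ``pa_id``.
    ``env`` maps environmental variable names to raw (untransformed)
    numeric values; missing values are NaN.
    """

    survey_id: str
    lon: float
    lat: float
    protection: str
    pa_id: str | None = None
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protection not in PROTECTION_RANK:
            raise ValidationError(
                f"survey {self.survey_id!r}: unknown protection code "
                f"{self.protection!r} (expected one of {PROTECTION_LEVELS})"
            )
        if not -180.0 <= float(self.lon) <= 180.0:
            raise ValidationError(
                f"survey {self.survey_id!r}: longitude {self.lon} out of [-180, 180]"
            )
        if not -90.0 <= float(self.lat) <= 90.0:
            raise ValidationError(
                f"survey {self.survey_id!r}: latitude {self.lat} out of [-90, 90]"
            )
        if self.protection != "NPA" and not self.pa_id:
            raise ValidationError(
                f"survey {self.survey_id!r}: protection {self.protection} requires a pa_id"
            )
        self.lon = float(self.lon)
        self.lat = float(self.lat)


@dataclass(frozen=True)
class SpeciesInfo:
    """Species identity plus IUCN red-list code (``None`` = not assessed)."""

    species_id: str
    iucn: str | None = None

    def __post_init__(self) -> None:
        if self.iucn is not None and self.iucn not in IUCN_CODES:
            raise ValidationError(
                f"species {self.species_id!r}: unknown IUCN code {self.iucn!r}"
            )


class OccurrenceMatrix:
    """Binary survey x species incidence table.

    Thin validated wrapper around a pandas DataFrame with survey ids on
    the index and species ids on the columns; cells are 0/1. Row sums
    are survey richness, column sums are species occurrence counts.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate survey ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species ids: {dups}")
        values = data.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary cell at survey {data.index[r]!r}, "
                f"species {data.columns[c]!r}: {data.iat[r, c]!r}"
            )
        self._data = data.astype(np.int8)

    # ------------------------------------------------------------------
    @property
    def surveys(self) -> list[str]:
        return list(self._data.index)

    @property
    def species(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def to_frame(self) -> pd.DataFrame:
        return self._data.copy()

    def values_bool(self) -> np.ndarray:
        """Boolean ndarray view (surveys x species)."""
        return self._data.to_numpy(dtype=bool)

    def richness(self) -> pd.Series:
        return self._data.sum(axis=1)

    def occurrence_counts(self) -> pd.Series:
        return self._data.sum(axis=0)

    def submatrix(
        self,
        surveys: Sequence[str] | None = None,
        species: Sequence[str] | None = None,
    ) -> "OccurrenceMatrix":
        data = self._data
        if surveys is not None:
            missing = set(surveys) - set(data.index)
            if missing:
                raise KeyError(f"unknown survey ids: {sorted(missing)}")
            data = data.loc[list(surveys)]
        if species is not None:
            data = data.loc[:, list(species)]
        return OccurrenceMatrix(data)

    def pooled(self, surveys: Iterable[str]) -> set[str]:
        """Set union of species present across the given surveys."""
        sub = self._data.loc[list(surveys)]
        mask = sub.to_numpy(dtype=bool).any(axis=0)
        return set(sub.columns[mask])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OccurrenceMatrix):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:
        n, s = self.shape
        return f"OccurrenceMatrix({n} surveys x {s} species)"


@dataclass
class RegionSpec:
    """A focal protected area plus buffered lower-protection neighbours.

    ``members`` maps protection level to survey ids: the focal PA's own
    surveys appear under ``focal_level``; every other member has strictly
    lower protection and lies within ``buffer_km`` of the focal PA.
    """

    region_id: str
    focal_pa: str
    focal_level: str
    buffer_km: float
    members: dict[str, list[str]]

    def __post_init__(self) -> None:
        if self.focal_level not in ("SPA", "RA"):
            raise ValidationError(
                f"region {self.region_id!r}: focal level must be SPA or RA, "
                f"got {self.focal_level!r}"
            )
        focal_rank = PROTECTION_RANK[self.focal_level]
        for level in self.members:
            if level not in PROTECTION_RANK:
                raise ValidationError(
                    f"region {self.region_id!r}: unknown level {level!r}"
                )
            if level != self.focal_level and PROTECTION_RANK[level] >= focal_rank:
                raise ValidationError(
                    f"region {self.region_id!r}: member level {level} is not "
                    f"strictly below focal level {self.focal_level}"
                )

    @property
    def usable(self) -> bool:
        """True when at least one lower-protection member is present."""
        return any(
            ids
            for level, ids in self.members.items()
            if level != self.focal_level
        )

    @property
    def member_ids(self) -> list[str]:
        out: list[str] = []
        for level in PROTECTION_LEVELS:
            out.extend(self.members.get(level, []))
        return out


@dataclass
class ComparisonPair:
    """One high-vs-low protection comparison inside a region."""

    region_id: str
    high_level: str
    low_level: str
    high_surveys: list[str]
    low_surveys: list[str]

    def __post_init__(self) -> None:
        if PROTECTION_RANK[self.high_level] <= PROTECTION_RANK[self.low_level]:
            raise ValidationError(
                f"pair {self.region_id!r}: {self.high_level} is not strictly "
                f"above {self.low_level}"
            )
        if not self.high_surveys or not self.low_surveys:
            raise ValidationError(
                f"pair {self.region_id!r} ({self.high_level}-{self.low_level}): "
                "both sides must be non-empty"
            )
        overlap = set(self.high_surveys) & set(self.low_surveys)
        if overlap:
            raise ValidationError(
                f"pair {self.region_id!r}: surveys on both sides: {sorted(overlap)}"
            )

    @property
    def label(self) -> str:
        return f"{self.high_level}-{self.low_level}"
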