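"""Assemble regions: focal protected areas plus buffered neighbours.

A *region* is a focal protected area (SPA or RA) together with every
survey of strictly lower protection whose great-circle distance to the
nearest focal survey is at most the buffer radius (10/50/100 km).
Protected-area geometry (polygons) is unavailable here, so distance to a
protected area is the minimum haversine distance to any survey inside it
— the only computable proxy when only survey coordinates exist.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .datamodel import (
    PROTECTION_RANK,
    ComparisonPair,
    RegionSpec,
    Survey,
    ValidationError,
)

__all__ = ["EARTH_RADIUS_KM", "haversine_km", "build_regions", "comparison_pairs"]

logger = logging.getLogger(__name__)

#: Mean Earth radius used for all great-circle distances.
EARTH_RADIUS_KM = 6371.0


def haversine_km(
    p1: tuple[float, float], p2: tuple[float, float]
) -> float:
    """Great-circle distance in km between two (lon, lat) points in degrees."""
    lon1, lat1 = p1
    lon2, lat2 = p2
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if not -180.0 <= lon <= 180.0 or not -90.0 <= lat <= 90.0:
            raise ValueError(f"coordinate out of range: lon={lon}, lat={lat}")
    return float(
        _haversine_arrays(
            np.asarray([lon1]), np.asarray([lat1]), np.asarray([lon2]), np.asarray([lat2])
        )[0]
    )


def _haversine_arrays(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _min_distance_to_focal(
    focal: Sequence[Survey], others: Sequence[Survey]
) -> np.ndarray:
    """Minimum distance (km) from each of `others` to the focal survey set."""
    flon = np.asarray([s.lon for s in focal])
    flat = np.asarray([s.lat for s in focal])
    olon = np.asarray([s.lon for s in others])
    olat = np.asarray([s.lat for s in others])
    # broadcast: (n_other, n_focal)
    d = _haversine_arrays(
        olon[:, None], olat[:, None], flon[None, :], flat[None, :]
    )
    return d.min(axis=1)


def build_regions(surveys: Sequence[Survey], buffer_km: float) -> list[RegionSpec]:
    """One region per focal protected area (both SPA and RA focals).

    Members are the focal PA's own surveys plus every survey of strictly
    lower protection within ``buffer_km`` of the nearest focal survey.
    Regions without any lower-protection member are still emitted (with
    ``usable == False``) so callers can log them.
    """
    if not any(s.protection != "NPA" for s in surveys):
        raise ValidationError("no protected survey: cannot build regions")

    # group protected surveys by protected area
    pa_surveys: dict[str, list[Survey]] = {}
    for s in surveys:
        if s.protection != "NPA":
            pa_surveys.setdefault(s.pa_id, []).append(s)

    regions: list[RegionSpec] = []
    for pa_id, focal in sorted(pa_surveys.items()):
        levels = {s.protection for s in focal}
        if len(levels) != 1:
            raise ValidationError(
                f"protected area {pa_id!r} mixes protection levels {sorted(levels)}"
            )
        focal_level = focal[0].protection
        focal_rank = PROTECTION_RANK[focal_level]
        lower = [s for s in surveys if PROTECTION_RANK[s.protection] < focal_rank]
        members: dict[str, list[str]] = {focal_level: [s.survey_id for s in focal]}
        if lower:
            dmin = _min_distance_to_focal(focal, lower)
            for s, d in zip(lower, dmin):
                if d <= buffer_km:
                    members.setdefault(s.protection, []).append(s.survey_id)
        region = RegionSpec(
            region_id=pa_id,
            focal_pa=pa_id,
            focal_level=focal_level,
            buffer_km=float(buffer_km),
            members=members,
        )
        if not region.usable:
            logger.warning(
                "region %s (%s focal) has no lower-protection member within %.0f km",
                pa_id,
                focal_level,
                buffer_km,
            )
        regions.append(region)
    return regions


def comparison_pairs(regions: Sequence[RegionSpec]) -> list[ComparisonPair]:
    """Emit SPA-RA, SPA-NPA and RA-NPA pairs wherever both sides have surveys."""
    pairs: list[ComparisonPair] = []
    for region in regions:
        if not region.usable:
            logger.info("region %s skipped: no lower-protection members", region.region_id)
            continue
        high = region.members.get(region.focal_level, [])
        for low_level in ("RA", "NPA"):
            if low_level == region.focal_level:
                continue
            low = region.members.get(low_level, [])
            if high and low:
                pairs.append(
                    ComparisonPair(
                        region_id=region.region_id,
                        high_level=region.focal_level,
                        low_level=low_level,
                        high_surveys=list(high),
                        low_surveys=list(low),
                    )
                )
    return pairs
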