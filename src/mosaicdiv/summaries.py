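"""Richness comparisons, Venn gamma-diversity shares, IUCN grouping, rarity filter.

The regional (gamma) species pool of a region with all three protection
levels is decomposed into the seven non-empty subsets of {SPA, RA, NPA}
membership — which fraction of the regional pool is unique to each
level, shared by two, or by all three. To remove effort bias, every
level is subsampled to the common minimum survey count before pooling,
and shares are averaged across iterations.

IUCN red-list codes are collapsed into three conservation groups:
CR/EN/VU/NT -> "Imperiled" (conservation-dependent), LC ->
"NotThreatened", DD or unassessed -> "NotAssessed".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .datamodel import (
    PROTECTION_LEVELS,
    IUCN_CODES,
    OccurrenceMatrix,
    RegionSpec,
    SpeciesInfo,
)
from .resampling import StandardizedResult

__all__ = [
    "THREAT_GROUPS",
    "VennShares",
    "classify_iucn",
    "rarity_filter",
    "venn_shares",
    "richness_comparison",
]

logger = logging.getLogger(__name__)

THREAT_GROUPS = ("Imperiled", "NotThreatened", "NotAssessed")

_IMPERILED = {"CR", "EN", "VU", "NT"}

#: The 7 non-empty subsets of the three protection levels, in report order.
VENN_SUBSETS = tuple(
    "&".join(combo)
    for size in (1, 2, 3)
    for combo in combinations(PROTECTION_LEVELS, size)
)


@dataclass
class VennShares:
    """Mean percentage of regional gamma richness per membership subset."""

    region_id: str
    shares: dict[str, float]
    gamma: float
    n_iter: int

    def __post_init__(self) -> None:
        s = sum(self.shares.values())
        if abs(s - 100.0) > 1e-9:
            raise ValueError(f"Venn shares sum to {s}, expected 100")


def classify_iucn(status: str | None) -> str:
    """Collapse an IUCN code into Imperiled / NotThreatened / NotAssessed."""
    if status is None or status == "":
        return "NotAssessed"
    if status in _IMPERILED:
        return "Imperiled"
    if status == "LC":
        return "NotThreatened"
    if status == "DD":
        return "NotAssessed"
    raise ValueError(f"unknown IUCN code {status!r}")


def rarity_filter(
    occ: OccurrenceMatrix, region: RegionSpec, min_occ: int = 3
) -> OccurrenceMatrix:
    """Drop region-rare species from the region's occurrence submatrix.

    A species is rare in a region when it occurs in at least one but
    fewer than ``min_occ`` of the region's member surveys. Species absent
    from the region entirely are retained (they carry no incidence signal
    and dropping them would make the filter depend on the global species
    list), so ``min_occ=1`` is the identity on the submatrix. Surveys are
    never dropped.
    """
    if min_occ < 1:
        raise ValueError(f"min_occ must be >= 1, got {min_occ}")
    sub = occ.submatrix(region.member_ids)
    counts = sub.occurrence_counts()
    keep = counts.index[(counts >= min_occ) | (counts == 0)]
    return sub.submatrix(species=list(keep))


def venn_shares(
    region: RegionSpec,
    occ: OccurrenceMatrix,
    n_iter: int,
    rng_seed: int,
    threat_filter: str | None = None,
    species_info: Sequence[SpeciesInfo] | None = None,
) -> VennShares | None:
    """Balanced seven-way decomposition of regional gamma diversity.

    Requires the region to hold surveys at all three protection levels
    (otherwise the region is skipped with a warning). Each iteration
    subsamples every level to the common minimum survey count, pools
    each level, and assigns each species of the iteration's gamma pool
    to one of the seven membership subsets; percentages of gamma are
    averaged across iterations. ``threat_filter`` restricts the species
    universe to one conservation group (requires ``species_info``).
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    missing = [lv for lv in PROTECTION_LEVELS if not region.members.get(lv)]
    if missing:
        logger.warning(
            "region %s skipped for Venn analysis: no surveys at %s",
            region.region_id,
            missing,
        )
        return None

    species = occ.species
    if threat_filter is not None:
        if threat_filter not in THREAT_GROUPS:
            raise ValueError(f"unknown threat group {threat_filter!r}")
        if species_info is None:
            raise ValueError("threat_filter requires species_info")
        status = {sp.species_id: sp.iucn for sp in species_info}
        species = [
            s for s in species if classify_iucn(status.get(s)) == threat_filter
        ]

    sub = occ.submatrix(region.member_ids, species=species)
    mat = sub.values_bool()
    index = {sid: k for k, sid in enumerate(sub.surveys)}
    level_rows = {
        lv: np.asarray([index[s] for s in region.members[lv]])
        for lv in PROTECTION_LEVELS
    }
    k = min(len(rows) for rows in level_rows.values())

    rng = np.random.default_rng(rng_seed)
    share_acc = np.zeros(7)
    gamma_acc = 0.0
    used = 0
    for _ in range(n_iter):
        pools = {}
        for lv, rows in level_rows.items():
            pick = rows if len(rows) == k else rng.choice(rows, size=k, replace=False)
            pools[lv] = mat[pick].any(axis=0)
        gamma_mask = pools["SPA"] | pools["RA"] | pools["NPA"]
        gamma = int(gamma_mask.sum())
        if gamma == 0:
            continue
        counts = _venn_counts(pools)
        share_acc += counts / gamma * 100.0
        gamma_acc += gamma
        used += 1
    if used == 0:
        logger.warning("region %s: empty gamma pool in every iteration", region.region_id)
        return None
    shares = dict(zip(VENN_SUBSETS, share_acc / used))
    return VennShares(
        region_id=region.region_id,
        shares=shares,
        gamma=gamma_acc / used,
        n_iter=used,
    )


def _venn_counts(pools: Mapping[str, np.ndarray]) -> np.ndarray:
    """Species counts of the 7 exclusive membership subsets (VENN_SUBSETS order)."""
    spa, ra, npa = pools["SPA"], pools["RA"], pools["NPA"]
    return np.asarray(
        [
            (spa & ~ra & ~npa).sum(),
            (~spa & ra & ~npa).sum(),
            (~spa & ~ra & npa).sum(),
            (spa & ra & ~npa).sum(),
            (spa & ~ra & npa).sum(),
            (~spa & ra & npa).sum(),
            (spa & ra & npa).sum(),
        ],
        dtype=float,
    )


def richness_comparison(
    results: Sequence[StandardizedResult],
) -> dict[str, float]:
    """Across-region test of the standardized richness difference.

    One-sample two-sided Wilcoxon signed-rank test of the region-level
    mean richness differences (high minus low protection) against zero.
    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used for n <= 25 without ties, the normal
    approximation with continuity correction otherwise.
    """
    if len(results) < 2:
        raise ValueError("insufficient regions: need >= 2 for a Wilcoxon test")
    deltas = np.asarray([r.delta_s for r in results], dtype=float)
    median = float(np.median(deltas))
    if np.all(deltas == 0):
        logger.warning("all richness differences are zero: degenerate Wilcoxon, p = 1")
        return {"median_delta_s": 0.0, "wilcoxon_p": 1.0, "n": len(deltas)}
    res = stats.wilcoxon(
        deltas, zero_method="wilcox", alternative="two-sided", correction=True
    )
    return {
        "median_delta_s": median,
        "wilcoxon_p": float(res.pvalue),
        "n": int(len(deltas)),
    }
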