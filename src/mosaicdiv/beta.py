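"""Pairwise Jaccard dissimilarity and its turnover/nestedness partition.

Compositional dissimilarity between two species pools is measured by the
Jaccard dissimilarity and additively split into two components with
distinct ecological meanings:

* **turnover** — species replacement between the pools, independent of
  any richness difference;
* **nestedness** (nestedness-resultant dissimilarity) — the part of the
  dissimilarity due to the poorer pool being a subset of the richer one.

With ``a`` shared species, ``b`` unique to the first pool and ``c``
unique to the second::

    total     = (b + c) / (a + b + c)
    turnover  = 2*min(b, c) / (a + 2*min(b, c))
    nestedness = |b - c| / (a + b + c) * a / (a + 2*min(b, c))

and ``total = turnover + nestedness`` holds exactly.  (Some printings of
the total-dissimilarity denominator read ``a + b + b``; that is a
typographical slip — additivity requires ``a + b + c``, the standard
Jaccard denominator.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairwiseCounts",
    "BetaPartition",
    "pairwise_counts",
    "jaccard_partition",
    "partition_sets",
    "partition_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairwiseCounts:
    """Set counts for one pairwise comparison: shared / only-first / only-second."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class BetaPartition:
    """Jaccard dissimilarity split into turnover + nestedness."""

    total: float
    turnover: float
    nestedness: float

    def __post_init__(self) -> None:
        for name in ("total", "turnover", "nestedness"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.total - (self.turnover + self.nestedness)) > 1e-12:
            raise ValueError(
                f"additivity violated: {self.total} != {self.turnover} + {self.nestedness}"
            )


def pairwise_counts(pool_a: Iterable[str], pool_b: Iterable[str]) -> PairwiseCounts:
    """Count shared and unique species between two pools."""
    sa, sb = set(pool_a), set(pool_b)
    return PairwiseCounts(a=len(sa & sb), b=len(sa - sb), c=len(sb - sa))


def jaccard_partition(counts: PairwiseCounts) -> BetaPartition:
    """Partition the Jaccard dissimilarity for one (a, b, c) triple.

    Degenerate case ``a == 0 and min(b, c) == 0`` (one pool empty): the
    comparison is pure richness loss, so total = 1, turnover = 0,
    nestedness = 1 (the limit of the formulas); logged as degenerate.

    Raises
    ------
    ValueError
        If ``a + b + c == 0`` (two empty pools — nothing to compare).
    """
    a, b, c = counts.a, counts.b, counts.c
    denom = a + b + c
    if denom == 0:
        raise ValueError("empty comparison: a + b + c = 0")
    m = min(b, c)
    total = (b + c) / denom
    tden = a + 2 * m
    if tden == 0:
        # one pool empty: a = 0, min(b, c) = 0, b + c > 0
        logger.debug("degenerate comparison (one empty pool): counts=%s", counts)
        return BetaPartition(total=1.0, turnover=0.0, nestedness=1.0)
    turnover = 2 * m / tden
    nestedness = abs(b - c) / denom * (a / tden)
    return BetaPartition(total=total, turnover=turnover, nestedness=nestedness)


def partition_sets(pool_a: Iterable[str], pool_b: Iterable[str]) -> BetaPartition:
    """Convenience: partition directly from two species pools."""
    return jaccard_partition(pairwise_counts(pool_a, pool_b))


def partition_matrix(pools: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """All pairwise partitions between labelled pools.

    Returns a tidy frame with one row per unordered pool pair and columns
    ``pool_a, pool_b, a, b, c, total, turnover, nestedness``.
    """
    labels = list(pools)
    sets = {k: set(v) for k, v in pools.items()}
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            counts = pairwise_counts(sets[la], sets[lb])
            part = jaccard_partition(counts)
            rows.append(
                {
                    "pool_a": la,
                    "pool_b": lb,
                    "a": counts.a,
                    "b": counts.b,
                    "c": counts.c,
                    "total": part.total,
                    "turnover": part.turnover,
                    "nestedness": part.nestedness,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# vectorised internals used by the resampling engine


def partition_components(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (total, turnover, nestedness) from count arrays.

    Comparisons with ``a + b + c == 0`` yield NaN in all components
    (callers decide whether that is an error or a skipped draw).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    denom = a + b + c
    m = np.minimum(b, c)
    tden = a + 2 * m
    with np.errstate(divide="ignore", invalid="ignore"):
        total = np.where(denom > 0, (b + c) / denom, np.nan)
        turnover = np.where(tden > 0, 2 * m / np.where(tden > 0, tden, 1), 0.0)
        nestedness = np.where(
            tden > 0,
            np.abs(b - c) / np.where(denom > 0, denom, 1) * a / np.where(tden > 0, tden, 1),
            # one pool empty -> pure nestedness
            1.0,
        )
    turnover = np.where(denom > 0, turnover, np.nan)
    nestedness = np.where(denom > 0, nestedness, np.nan)
    return total, turnover, nestedness
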