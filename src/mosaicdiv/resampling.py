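"""Effort standardization, curveball null models, SES and Fisher combination.

Survey effort differs between the two sides of a protection comparison,
so every statistic is computed on balanced random subsamples: each
iteration draws the minimum side count from both sides without
replacement, pools each side's occurrences (set union) and partitions
the Jaccard dissimilarity between the pooled sides; across-iteration
means are reported.

Significance against a random-assembly expectation uses the curveball
algorithm: a Markov chain on binary matrices that preserves every row
sum (survey richness) and column sum (species frequency) while shuffling
co-occurrence structure. The standardized effect size

    SES = (observed - mean(null)) / SD(null)

measures departure from the null; |SES| > 1.96 flags two-sided
significance at alpha = 0.05. Permutation p-values use the add-one rule
(1 + r) / (1 + n) so they are never zero; region-level p-values are
combined across regions with Fisher's method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .beta import BetaPartition, partition_components
from .datamodel import ComparisonPair, OccurrenceMatrix

__all__ = [
    "StandardizedResult",
    "NullSummary",
    "standardized_subsample",
    "curveball_shuffle",
    "null_test",
    "fisher_combine",
]

logger = logging.getLogger(__name__)

COMPONENTS = ("total", "turnover", "nestedness")


@dataclass
class StandardizedResult:
    """Across-iteration means of the effort-standardized statistics."""

    pair: ComparisonPair
    n_per_side: int
    beta: BetaPartition
    delta_s: float
    n_iter: int
    seed: int


@dataclass
class NullSummary:
    """Observed statistic versus its curveball null distribution."""

    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    p_greater: float
    p_less: float


# ----------------------------------------------------------------------
# effort-standardized subsampling


def _subsample_pool(
    mat: np.ndarray, k: int, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Pooled occurrence (n_iter x S bool) of k rows drawn without replacement."""
    n, s = mat.shape
    if k == n:
        return np.broadcast_to(mat.any(axis=0), (n_iter, s))
    r = rng.random((n_iter, n))
    idx = np.argpartition(r, k - 1, axis=1)[:, :k]
    return mat[idx].any(axis=1)


def _subsample_means(
    high: np.ndarray, low: np.ndarray, n_iter: int, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """Mean (total, turnover, nestedness, delta_S) over balanced subsamples."""
    k = min(high.shape[0], low.shape[0])
    ph = _subsample_pool(high, k, n_iter, rng)
    pl = _subsample_pool(low, k, n_iter, rng)
    a = (ph & pl).sum(axis=1)
    b = (ph & ~pl).sum(axis=1)
    c = (pl & ~ph).sum(axis=1)
    total, turnover, nestedness = partition_components(a, b, c)
    if np.isnan(total).all():
        raise ValueError("all subsample iterations had two empty pools")
    delta_s = ph.sum(axis=1) - pl.sum(axis=1)
    return (
        float(np.nanmean(total)),
        float(np.nanmean(turnover)),
        float(np.nanmean(nestedness)),
        float(delta_s.mean()),
    )


def standardized_subsample(
    pair: ComparisonPair,
    occ: OccurrenceMatrix,
    n_iter: int,
    rng_seed: int,
) -> StandardizedResult:
    """Balanced subsampling of the two sides of a comparison.

    Each of ``n_iter`` iterations draws ``min(|high|, |low|)`` surveys
    without replacement from each side, pools each side and partitions
    the Jaccard dissimilarity between the pooled sets; the reported
    result is the across-iteration mean. ``delta_s`` is the mean pooled
    richness difference (high minus low). Fully reproducible from
    ``rng_seed``.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(rng_seed)
    sub = occ.submatrix(list(pair.high_surveys) + list(pair.low_surveys))
    mat = sub.values_bool()
    nh = len(pair.high_surveys)
    total, turnover, _, delta_s = _subsample_means(mat[:nh], mat[nh:], n_iter, rng)
    # per-iteration additivity makes mean nestedness = mean total - mean
    # turnover exactly; reconstructing it keeps the invariant bit-exact
    turnover = min(turnover, total)
    return StandardizedResult(
        pair=pair,
        n_per_side=min(nh, mat.shape[0] - nh),
        beta=BetaPartition(total=total, turnover=turnover, nestedness=total - turnover),
        delta_s=delta_s,
        n_iter=n_iter,
        seed=rng_seed,
    )


# ----------------------------------------------------------------------
# curveball null model


def _curveball_steps(mat: np.ndarray, n_steps: int, rng: np.random.Generator) -> None:
    """In-place curveball trades on a boolean matrix.

    Each step picks two distinct rows, finds the species unique to each,
    pools them and randomly re-splits the pool between the rows, keeping
    each row's count of unique species. Row and column sums are invariant.
    """
    n_rows = mat.shape[0]
    if n_rows < 2:
        return
    pick = rng.integers(0, n_rows, size=(n_steps, 2))
    for i, j in pick:
        if i == j:
            continue
        r1 = mat[i]
        r2 = mat[j]
        only1 = np.flatnonzero(r1 & ~r2)
        only2 = np.flatnonzero(r2 & ~r1)
        n1 = only1.size
        if n1 == 0 or only2.size == 0:
            continue
        pool = np.concatenate((only1, only2))
        rng.shuffle(pool)
        mat[i, pool] = False
        mat[j, pool] = False
        mat[i, pool[:n1]] = True
        mat[j, pool[n1:]] = True


def curveball_shuffle(
    occ: OccurrenceMatrix | np.ndarray,
    n_steps: int,
    rng: np.random.Generator | int,
) -> OccurrenceMatrix | np.ndarray:
    """Return a margin-preserving shuffle of a binary matrix.

    Matrices with no feasible trade (e.g. all-ones) are returned
    unchanged. Accepts either an :class:`OccurrenceMatrix` or a plain
    ndarray and returns the same kind.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if isinstance(occ, OccurrenceMatrix):
        frame = occ.to_frame()
        mat = frame.to_numpy(dtype=bool)
        _curveball_steps(mat, n_steps, rng)
        frame.loc[:, :] = mat.astype(np.int8)
        return OccurrenceMatrix(frame)
    mat = np.array(occ, dtype=bool)
    _curveball_steps(mat, n_steps, rng)
    return mat.astype(occ.dtype if hasattr(occ, "dtype") else np.int8)


# ----------------------------------------------------------------------
# null test (SES + permutation p)


def _summary(observed: float, null: np.ndarray, n_null: int) -> NullSummary:
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_null > 1 else 0.0
    if null_sd > 0:
        ses = (observed - null_mean) / null_sd
    elif observed == null_mean:
        ses = 0.0
    else:
        ses = float(np.inf) if observed > null_mean else float(-np.inf)
        logger.warning("degenerate null (sd = 0, observed != mean): ses set to %s", ses)
    r_ge = int((null >= observed).sum())
    r_le = int((null <= observed).sum())
    p_greater = (1 + r_ge) / (1 + n_null)
    p_less = (1 + r_le) / (1 + n_null)
    p_two = min(1.0, 2.0 * min(p_greater, p_less))
    return NullSummary(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        ses=float(ses),
        p_value=p_two,
        p_greater=p_greater,
        p_less=p_less,
    )


def null_test(
    pair: ComparisonPair,
    occ: OccurrenceMatrix,
    n_null: int,
    n_iter: int,
    rng_seed: int,
    burn_in_factor: int = 5,
    steps_per_draw: int | None = None,
    observed: StandardizedResult | None = None,
) -> dict[str, NullSummary]:
    """Curveball null test of the standardized beta-diversity statistics.

    The observed value is the across-iteration mean from
    :func:`standardized_subsample`. The null distribution recomputes the
    same statistic on ``n_null`` successive states of a curveball chain
    run on the pair's occurrence submatrix (burn-in of
    ``burn_in_factor * n_rows`` trades, then ``steps_per_draw`` trades —
    default: one per row — between saved states). Returns one
    :class:`NullSummary` per component (total, turnover, nestedness).
    """
    if n_null < 1:
        raise ValueError(f"n_null must be >= 1, got {n_null}")
    rng = np.random.default_rng(rng_seed)
    obs_seed = int(rng.integers(0, 2**31 - 1))
    if observed is None:
        observed = standardized_subsample(pair, occ, n_iter, obs_seed)

    sub = occ.submatrix(list(pair.high_surveys) + list(pair.low_surveys))
    mat = sub.values_bool().copy()
    nh = len(pair.high_surveys)
    n_rows = mat.shape[0]
    if steps_per_draw is None:
        steps_per_draw = n_rows

    _curveball_steps(mat, burn_in_factor * n_rows, rng)
    null_vals = np.empty((n_null, 3))
    for t in range(n_null):
        _curveball_steps(mat, steps_per_draw, rng)
        total, turnover, nestedness, _ = _subsample_means(
            mat[:nh], mat[nh:], n_iter, rng
        )
        null_vals[t] = (total, turnover, nestedness)

    obs_vals = (observed.beta.total, observed.beta.turnover, observed.beta.nestedness)
    return {
        comp: _summary(obs, null_vals[:, k], n_null)
        for k, (comp, obs) in enumerate(zip(COMPONENTS, obs_vals))
    }


# ----------------------------------------------------------------------
# Fisher combination


def fisher_combine(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's combined probability test.

    X^2 = -2 * sum(ln p_i) is referred to a chi-square distribution with
    2k degrees of freedom. Returns ``(statistic, combined_p)``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError(f"p-values must lie in (0, 1], got {p}")
    x2 = float(-2.0 * np.log(p).sum())
    return x2, float(stats.chi2.sf(x2, df=2 * p.size))
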