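"""Environmental dissimilarity, PCoA and (partial) distance-based RDA.

The survey-level analysis asks how much of the species turnover between
surveys of one region is attributable to protection level versus to
environmental conditions. The response is a survey x survey distance
matrix (the turnover component of the pairwise Jaccard partition); it is
embedded by principal coordinates analysis (PCoA, Gower-centred
eigendecomposition), and the coordinates are regressed on predictors
(protection dummies, environmental PCoA axes) — distance-based
redundancy analysis. "Partial" dbRDA residualizes response and
predictors on a conditioning block first, isolating e.g. the exclusive
effect of protection after accounting for environment. Significance
comes from ANOVA-like permutation tests (permuting reduced-model
residuals when conditioned, free row permutation otherwise).

Non-Euclidean distance matrices (Jaccard-family distances usually are)
produce negative PCoA eigenvalues; the Lingoes correction (adding a
constant to all squared off-diagonal distances) restores a Euclidean
embedding before the regression step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .beta import partition_components
from .datamodel import ComparisonPair, OccurrenceMatrix

__all__ = [
    "PCoAResult",
    "OrdinationResult",
    "EnvDistanceResult",
    "pcoa",
    "lingoes_correction",
    "dbrda",
    "dbrda_marginal",
    "survey_turnover_distance",
    "env_pcoa_axes",
    "env_distance",
    "turnover_env_regression",
]

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-8


@dataclass
class PCoAResult:
    """Eigenvalues (descending, trivial zero included) and coordinates.

    ``coordinates`` holds only axes with eigenvalue > tol * max(eig),
    scaled by sqrt(eigenvalue).
    """

    eigenvalues: np.ndarray
    coordinates: np.ndarray
    correction: str | None = None


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray
    site_scores: np.ndarray
    r2: float
    adj_r2: float
    f_stat: float
    perm_p: float
    marginal: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class EnvDistanceResult:
    """Mean balanced-subsample environmental distance for one comparison."""

    pair: ComparisonPair
    env_distance: float
    n_iter: int
    regression: dict[str, float] | None = None


# ----------------------------------------------------------------------
# PCoA


def _check_distance_matrix(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {d.shape}")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def pcoa(dist: np.ndarray) -> PCoAResult:
    """Principal coordinates analysis via Gower-centred eigendecomposition.

    Negative eigenvalues (non-Euclidean input) are retained in
    ``eigenvalues`` but excluded from ``coordinates``.
    """
    d = _check_distance_matrix(dist)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = (g + g.T) / 2.0
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    scale = max(abs(eigval[0]), abs(eigval[-1]), 1.0)
    keep = eigval > _EIG_TOL * scale
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return PCoAResult(eigenvalues=eigval, coordinates=coords)


def lingoes_correction(dist: np.ndarray) -> tuple[np.ndarray, float]:
    """Additive constant making a distance matrix Euclidean-embeddable.

    Returns ``(corrected, c1)`` where ``corrected[i, j]^2 = dist[i, j]^2
    + 2*c1`` off the diagonal and ``c1 = -min(eigenvalue)`` of the Gower
    form. If the input is already Euclidean it is returned unchanged.
    """
    d = _check_distance_matrix(dist)
    eigval = pcoa(d).eigenvalues
    lam_min = eigval.min()
    if lam_min >= -_EIG_TOL * max(abs(eigval[0]), 1.0):
        return d, 0.0
    c1 = float(-lam_min)
    d2 = d**2 + 2.0 * c1
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2), c1


def _embed(dist: np.ndarray, neg_eig: str) -> PCoAResult:
    res = pcoa(dist)
    scale = max(abs(res.eigenvalues[0]), 1.0)
    if res.eigenvalues.min() < -_EIG_TOL * scale:
        if neg_eig == "lingoes":
            corrected, c1 = lingoes_correction(dist)
            res = pcoa(corrected)
            res.correction = f"lingoes(c1={c1:.6g})"
            logger.info("applied Lingoes correction, c1=%.6g", c1)
        elif neg_eig == "drop":
            res.correction = "dropped_negative_axes"
        else:
            raise ValueError(f"unknown negative-eigenvalue strategy {neg_eig!r}")
    return res


# ----------------------------------------------------------------------
# dbRDA


def _orthobasis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    if x.size == 0:
        return np.empty((x.shape[0], 0))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return u[:, s > tol]


def _as_design(x, n: int, name: str) -> np.ndarray:
    if x is None:
        return np.empty((n, 0))
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != n:
        raise ValueError(f"{name} has {arr.shape[0]} rows, expected {n}")
    # drop constant columns (they carry no constraint beyond the intercept)
    keep = arr.std(axis=0) > 1e-12
    if not keep.all():
        logger.warning("%s: dropped %d constant column(s)", name, int((~keep).sum()))
    return arr[:, keep]


def dbrda(
    response_dist: np.ndarray,
    predictors,
    condition=None,
    n_perm: int = 999,
    rng_seed: int = 0,
    neg_eig: str = "lingoes",
) -> OrdinationResult:
    """Distance-based redundancy analysis with optional conditioning.

    ``r2`` is the (semi-partial) fraction of total PCoA inertia explained
    by the predictors after removing the conditioning block; ``adj_r2``
    applies the Ezekiel degrees-of-freedom correction. The pseudo-F
    statistic is tested by permutation: reduced-model residual rows are
    permuted (and re-residualized) when a condition is given, otherwise
    rows are permuted freely.
    """
    emb = _embed(response_dist, neg_eig)
    y = emb.coordinates
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    total_inertia = float((yc**2).sum())
    if total_inertia <= 0:
        raise ValueError("response distances carry no variance")

    x = _as_design(predictors, n, "predictors")
    z = _as_design(condition, n, "condition")
    if x.shape[1] == 0:
        raise ValueError("no non-constant predictor columns")

    qz = _orthobasis(np.column_stack([np.ones((n, 1)), z]))
    pz = qz.shape[1] - 1  # conditioning df beyond the intercept
    yr = yc - qz @ (qz.T @ yc)
    xr = x - qz @ (qz.T @ x)
    # a predictor column (numerically) inside the conditioned space carries
    # no constraint; keep only columns retaining real residual variance
    xnorm = np.linalg.norm(x, axis=0)
    keep = np.linalg.norm(xr, axis=0) > 1e-8 * np.maximum(xnorm, 1e-30)
    xr = xr[:, keep]
    qx = _orthobasis(xr)
    q = qx.shape[1]
    if q == 0:
        raise ValueError("predictors are collinear with the condition")
    if q + pz + 1 >= n:
        raise ValueError(
            f"more predictors ({q}) + condition ({pz}) than surveys allow (n={n})"
        )

    def _f_and_ss(ymat: np.ndarray) -> tuple[float, float]:
        proj = qx.T @ ymat
        ss_ex = float((proj**2).sum())
        ss_res = float((ymat**2).sum()) - ss_ex
        df_res = n - 1 - pz - q
        f = (ss_ex / q) / (ss_res / df_res) if ss_res > 0 else np.inf
        return f, ss_ex

    f_obs, ss_ex = _f_and_ss(yr)
    r2 = ss_ex / total_inertia
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1 - pz) / (n - 1 - pz - q)

    rng = np.random.default_rng(rng_seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = yr[perm]
        if pz > 0:
            yp = yp - qz @ (qz.T @ yp)
        f_p, _ = _f_and_ss(yp)
        if f_p >= f_obs:
            exceed += 1
    perm_p = (1 + exceed) / (1 + n_perm)

    return OrdinationResult(
        eigenvalues=emb.eigenvalues,
        site_scores=y,
        r2=float(r2),
        adj_r2=float(adj_r2),
        f_stat=float(f_obs),
        perm_p=float(perm_p),
    )


def dbrda_marginal(
    response_dist: np.ndarray,
    terms: Mapping[str, np.ndarray],
    n_perm: int = 999,
    rng_seed: int = 0,
    neg_eig: str = "lingoes",
) -> OrdinationResult:
    """Joint dbRDA of all terms plus marginal (each | all others) effects.

    The overall model uses every term as predictor with no condition;
    each marginal effect conditions that term on all the others. The
    ``marginal`` map holds ``r2_share`` (semi-partial R^2 of total
    inertia), pseudo-F and permutation p per term.
    """
    names = list(terms)

    def _col(v) -> np.ndarray:
        arr = np.asarray(v, dtype=float)
        return arr[:, None] if arr.ndim == 1 else arr

    blocks = {k: _col(v) for k, v in terms.items()}
    joint = np.column_stack([blocks[k] for k in names])
    rng = np.random.default_rng(rng_seed)
    overall = dbrda(
        response_dist,
        joint,
        condition=None,
        n_perm=n_perm,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        neg_eig=neg_eig,
    )
    for name in names:
        others = [blocks[k] for k in names if k != name]
        cond = np.column_stack(others) if others else None
        try:
            res = dbrda(
                response_dist,
                blocks[name],
                condition=cond,
                n_perm=n_perm,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
                neg_eig=neg_eig,
            )
            overall.marginal[name] = {
                "r2_share": res.r2,
                "f": res.f_stat,
                "perm_p": res.perm_p,
            }
        except ValueError as exc:
            logger.warning("marginal term %s skipped: %s", name, exc)
            overall.marginal[name] = {"r2_share": 0.0, "f": np.nan, "perm_p": np.nan}
    return overall


# ----------------------------------------------------------------------
# distances used by the pipeline


def survey_turnover_distance(occ: OccurrenceMatrix) -> np.ndarray:
    """Pairwise turnover-component distance between individual surveys."""
    mat = occ.values_bool()
    inter = (mat.astype(np.int32) @ mat.T.astype(np.int32)).astype(float)
    rich = mat.sum(axis=1).astype(float)
    a = inter
    b = rich[:, None] - inter
    c = rich[None, :] - inter
    _, turnover, _ = partition_components(a, b, c)
    turnover = np.nan_to_num(turnover, nan=0.0)
    np.fill_diagonal(turnover, 0.0)
    return turnover


def env_pcoa_axes(env_table: pd.DataFrame, n_axes: int = 2) -> np.ndarray:
    """First PCoA axes of the Euclidean distance between log1p env rows."""
    values = np.log1p(env_table.to_numpy(dtype=float))
    dist = squareform(pdist(values))
    coords = pcoa(dist).coordinates
    if coords.shape[1] == 0:
        raise ValueError("environmental table carries no variance")
    return coords[:, : min(n_axes, coords.shape[1])]


def env_distance(
    pair: ComparisonPair,
    env_table: pd.DataFrame,
    n_iter: int,
    rng_seed: int,
) -> EnvDistanceResult | None:
    """Balanced-subsample environmental distance between the two sides.

    Per iteration, ``min`` side-count surveys are drawn from each side's
    environmentally complete surveys; the Euclidean distance between the
    two sides' centroid vectors of ln(x+1)-transformed variables is
    averaged across iterations. Surveys with missing environmental
    values are dropped with a warning; a side with fewer than two
    complete surveys skips the pair (returns None).
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(rng_seed)

    def _complete(ids: Sequence[str]) -> pd.DataFrame:
        block = env_table.loc[[i for i in ids if i in env_table.index]]
        complete = block.dropna()
        dropped = len(ids) - len(complete)
        if dropped:
            logger.warning(
                "pair %s %s: dropped %d survey(s) with missing environment",
                pair.region_id,
                pair.label,
                dropped,
            )
        return complete

    high = _complete(pair.high_surveys)
    low = _complete(pair.low_surveys)
    if len(high) < 2 or len(low) < 2:
        logger.warning(
            "pair %s %s skipped: <2 environmentally complete surveys on a side",
            pair.region_id,
            pair.label,
        )
        return None

    hv = np.log1p(high.to_numpy(dtype=float))
    lv = np.log1p(low.to_numpy(dtype=float))
    k = min(len(hv), len(lv))
    dists = np.empty(n_iter)
    for t in range(n_iter):
        hc = hv[rng.choice(len(hv), size=k, replace=False)].mean(axis=0)
        lc = lv[rng.choice(len(lv), size=k, replace=False)].mean(axis=0)
        dists[t] = np.linalg.norm(hc - lc)
    return EnvDistanceResult(pair=pair, env_distance=float(dists.mean()), n_iter=n_iter)


def turnover_env_regression(
    points: Sequence[tuple[float, float]],
) -> dict[str, float]:
    """OLS of turnover on environmental distance across regions.

    Returns slope, intercept, r2 and the two-sided p-value of the slope.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (env_distance, turnover) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.std(x) == 0:
        raise ValueError("zero variance in environmental distance")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "n": int(len(x)),
    }
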