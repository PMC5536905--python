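"""Fuzzy c-means clustering of z-scored expression time profiles.

Follows the mfuzz convention: per-profile z-scoring (so only the *shape* of
a time course matters), Euclidean distance, soft memberships with fuzzifier
m > 1, and a data-driven fuzzifier estimate (Schwammle-Jensen rule).  The
reference configuration uses c = 6 clusters with a data-estimated
fuzzifier (about 2.54 at full-proteome scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import TimeProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_C = 6
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000
DEFAULT_RESTARTS = 10


def zscore_profiles(profiles: TimeProfileMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-row standardization to mean 0, SD 1 (population SD).

    Rows with any missing time point, fewer than two values, or zero variance
    are dropped (logged); the survivors are complete and finite.
    """
    values = profiles.values if isinstance(profiles, TimeProfileMatrix) else profiles
    complete = values.dropna()
    n_dropped_missing = len(values) - len(complete)
    sd = complete.std(axis=1, ddof=0)
    keep = (sd > 0) & (complete.shape[1] >= 2)
    n_dropped_const = int((~keep).sum())
    if n_dropped_missing or n_dropped_const:
        logger.info("zscore_profiles: dropped %d rows with missing values, "
                    "%d constant rows", n_dropped_missing, n_dropped_const)
    z = complete[keep]
    return z.sub(z.mean(axis=1), axis=0).div(sd[keep], axis=0)


def estimate_fuzzifier(n: int, d: int) -> float:
    """Dimension-based fuzzifier estimate (Schwammle-Jensen / mfuzz mestimate).

    m = 1 + (1418/n + 22.05) d^-2 + (12.33/n + 0.243) d^(-0.0406 ln n - 0.1134)
    """
    if n < 2 or d < 2:
        raise ValueError("need n >= 2 rows and d >= 2 dimensions")
    return float(1.0 + (1418.0 / n + 22.05) * d ** -2.0
                 + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134))


@dataclass
class FuzzyClustering:
    """Soft partition: centroids, memberships summing to 1 per row, trace."""

    centroids: np.ndarray       # c x T
    membership: pd.DataFrame    # n x c, rows sum to 1
    m: float
    c: int
    objective_trace: list[float]


def _memberships(X: np.ndarray, V: np.ndarray, m: float) -> np.ndarray:
    d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(-1)
    zero = d2 <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        w = d2 ** (-1.0 / (m - 1.0))
        u = w / w.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if hit.any():
        # a point coinciding with a centroid belongs to it entirely
        u[hit] = 0.0
        u[hit, zero[hit].argmax(axis=1)] = 1.0
    return u


def _objective(X: np.ndarray, V: np.ndarray, U: np.ndarray, m: float) -> float:
    d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(-1)
    return float((U ** m * d2).sum())


def fuzzy_cmeans(data: pd.DataFrame | np.ndarray, c: int = DEFAULT_C,
                 m: float = 2.54, seed: int | None = None,
                 tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                 restarts: int = DEFAULT_RESTARTS) -> FuzzyClustering:
    """Fuzzy c-means with Euclidean distance and random-row initialization.

    Standard alternating updates: membership u_ic proportional to
    (1/||x_i - v_c||^2)^(1/(m-1)) normalized over clusters, centroids as the
    u^m-weighted means.  Runs ``restarts`` seeded initializations and keeps
    the best final objective.  Stops when the largest centroid shift is
    below ``tol``.
    """
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    index = data.index if isinstance(data, pd.DataFrame) else pd.RangeIndex(len(X))
    if len(X) < c:
        raise ValueError("fewer rows than clusters")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(restarts, 1)):
        rng = np.random.default_rng(child)
        V = X[rng.choice(len(X), size=c, replace=False)].copy()
        trace = []
        for _ in range(max_iter):
            U = _memberships(X, V, m)
            Um = U ** m
            V_new = (Um.T @ X) / Um.sum(axis=0)[:, None]
            trace.append(_objective(X, V_new, U, m))
            shift = np.abs(V_new - V).max()
            V = V_new
            if shift < tol:
                break
        U = _memberships(X, V, m)
        final = _objective(X, V, U, m)
        if best is None or final < best[0]:
            best = (final, V, U, trace)
    _, V, U, trace = best
    membership = pd.DataFrame(U, index=index,
                              columns=[f"cluster_{i+1}" for i in range(c)])
    return FuzzyClustering(V, membership, m=m, c=c, objective_trace=trace)


def assign_clusters(clustering: FuzzyClustering, min_membership: float = 0.5
                    ) -> tuple[pd.Series, pd.Index]:
    """Hard labels by argmax membership; rows below the threshold unassigned.

    Argmax ties break toward the lowest cluster index.  Returns
    ``(labels, unassigned_index)``; labels are 1-based cluster numbers with
    unassigned rows excluded.
    """
    U = clustering.membership
    top = U.max(axis=1)
    labels = U.to_numpy().argmax(axis=1) + 1
    assigned = top >= min_membership
    out = pd.Series(labels, index=U.index, name="cluster")[assigned]
    return out, U.index[~assigned]
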