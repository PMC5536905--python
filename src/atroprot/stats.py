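"""S0-moderated statistics with permutation-based FDR, plus Storey q-values.

The test statistic is the SAM-style moderated t: the group difference divided
by (standard error + S0).  The fudge factor S0 damps the significance of
tiny-variance features, which otherwise dominate the tails of the plain t at
small n.  The FDR of a candidate cutoff theta is estimated as the median,
over label permutations (two-sample) or sign flips (one-sample), of the
number of permuted |d| exceeding theta, divided by the observed exceedance
count, with pi0 fixed at 1 (conservative).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_S0 = 0.1
DEFAULT_N_PERM = 250


# ---------------------------------------------------------------------------
# Moderated statistic
# ---------------------------------------------------------------------------

def moderated_statistic(group_a, group_b=None, s0: float = DEFAULT_S0
                        ) -> tuple[float, float]:
    """Return ``(d_stat, effect)`` for one feature.

    Two-sample: ``d = (mean_a - mean_b) / (se_pooled + s0)`` with the pooled
    two-sample standard error.  One-sample (``group_b is None``): the mean is
    tested against zero, ``d = mean / (sd/sqrt(n) + s0)``.  Fewer than two
    valid values per group yields ``(nan, nan)`` (not-testable), no exception.
    """
    a = np.asarray(group_a, dtype=float)
    a = a[~np.isnan(a)]
    if group_b is None:
        if a.size < 2:
            return math.nan, math.nan
        se = a.std(ddof=1) / math.sqrt(a.size)
        eff = float(a.mean())
        return eff / (se + s0), eff
    b = np.asarray(group_b, dtype=float)
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return math.nan, math.nan
    eff = float(a.mean() - b.mean())
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) \
        / (a.size + b.size - 2)
    se = math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    return eff / (se + s0), eff


def _two_sample_d(X: np.ndarray, a_mask: np.ndarray, s0: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NaN-aware two-sample d over rows. Returns (d, effect, n_used)."""
    A, B = X[:, a_mask], X[:, ~a_mask]
    va, vb = ~np.isnan(A), ~np.isnan(B)
    na, nb = va.sum(1), vb.sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nansum(A, 1) / na
        mb = np.nansum(B, 1) / nb
        ssa = np.nansum((A - ma[:, None]) ** 2 * va, 1)
        ssb = np.nansum((B - mb[:, None]) ** 2 * vb, 1)
        sp2 = (ssa + ssb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        eff = ma - mb
        d = eff / (se + s0)
    bad = (na < 2) | (nb < 2)
    d[bad] = np.nan
    eff[bad] = np.nan
    return d, eff, na + nb


def _one_sample_d(X: np.ndarray, signs: np.ndarray, s0: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NaN-aware one-sample d of sign-flipped rows vs zero."""
    Y = X * signs[None, :]
    valid = ~np.isnan(Y)
    n = valid.sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.nansum(Y, 1) / n
        ss = np.nansum((Y - m[:, None]) ** 2 * valid, 1)
        sd = np.sqrt(ss / (n - 1))
        se = sd / np.sqrt(n)
        d = m / (se + s0)
    bad = n < 2
    d[bad] = np.nan
    m = np.where(bad, np.nan, m)
    return d, m, n


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------

@dataclass
class PermutationFdrResult:
    """Per-id moderated test results plus the |d| cutoff achieving the FDR."""

    table: pd.DataFrame            # id-indexed: effect, d_stat, p_plain, n_used, significant
    fdr_threshold_stat: float
    fdr_curve: pd.DataFrame        # threshold, n_observed, median_false, fdr
    n_permutations: int
    exhaustive: bool


def _two_sample_masks(n: int, na: int, n_perm, rng: np.random.Generator
                      ) -> tuple[np.ndarray, bool]:
    total = math.comb(n, na)
    if n_perm == "exhaustive" or total <= n_perm:
        if n_perm != "exhaustive" and total < n_perm:
            logger.info("permutation space (%d) smaller than n_perm=%s; "
                        "enumerating exhaustively", total, n_perm)
        masks = np.zeros((total, n), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), na)):
            masks[i, list(combo)] = True
        return masks, True
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=na, replace=False)] = True
    return masks, False


def _sign_matrix(n: int, n_perm, rng: np.random.Generator
                 ) -> tuple[np.ndarray, bool]:
    total = 2 ** n
    if n_perm == "exhaustive" or total <= n_perm:
        if n_perm != "exhaustive" and total < n_perm:
            logger.info("sign-flip space (%d) smaller than n_perm=%s; "
                        "enumerating exhaustively", total, n_perm)
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        return signs, True
    return rng.choice((1.0, -1.0), size=(n_perm, n)), False


def permutation_fdr(values: pd.DataFrame, labels=None, *,
                    s0: float = DEFAULT_S0, target_fdr: float = 0.05,
                    n_perm=DEFAULT_N_PERM, seed: int | None = None,
                    groups: tuple | None = None) -> PermutationFdrResult:
    """Moderated test of every row of *values* with permutation FDR control.

    Two-sample mode: *labels* assigns each column to one of two groups and
    the effect is mean(first group) - mean(second group); pass
    ``groups=(a, b)`` to fix the orientation (e.g. ``("denervated",
    "control")`` for den/ctrl effects), otherwise first-seen order is used.
    Group labels are permuted over columns.  One-sample mode (``labels is None``):
    each row is tested against zero and permutations flip column signs.
    When the permutation space has no more than ``n_perm`` elements it is
    enumerated exhaustively (the identity relabelling included).

    The significant set is the largest set of ids whose estimated FDR is at
    or below ``target_fdr``; ties in |d| at the cutoff are all included.
    """
    X = values.to_numpy(dtype=float)
    ids = values.index
    rng = np.random.default_rng(seed)

    if labels is not None:
        labels = np.asarray(labels)
        if groups is None:
            groups = tuple(pd.unique(labels))
        if len(groups) != 2 or set(groups) != set(pd.unique(labels)):
            raise ValueError(f"need exactly 2 groups, got {list(pd.unique(labels))}")
        a_mask = labels == groups[0]
        na = int(a_mask.sum())
        d_obs, eff, n_used = _two_sample_d(X, a_mask, s0)
        t_plain = _two_sample_d(X, a_mask, 0.0)[0]
        masks, exhaustive = _two_sample_masks(X.shape[1], na, n_perm, rng)
        perm_d = np.empty((len(masks), X.shape[0]))
        for i, m in enumerate(masks):
            perm_d[i] = _two_sample_d(X, m, s0)[0]
        df = n_used - 2
    else:
        d_obs, eff, n_used = _one_sample_d(X, np.ones(X.shape[1]), s0)
        t_plain = _one_sample_d(X, np.ones(X.shape[1]), 0.0)[0]
        signs, exhaustive = _sign_matrix(X.shape[1], n_perm, rng)
        perm_d = np.empty((len(signs), X.shape[0]))
        for i, s in enumerate(signs):
            perm_d[i] = _one_sample_d(X, s, s0)[0]
        df = n_used - 1

    # plain two-sided p from the unmoderated t reference (s0 = 0)
    p_plain = np.full(X.shape[0], np.nan)
    testable = ~np.isnan(d_obs)
    p_plain[testable] = 2.0 * sps.t.sf(np.abs(t_plain[testable]),
                                       np.maximum(df[testable], 1))

    abs_obs = np.abs(d_obs[testable])
    abs_perm = np.abs(perm_d)[:, testable]
    thresholds = np.unique(abs_obs)[::-1]
    obs_sorted = np.sort(abs_obs)
    perm_sorted = np.sort(abs_perm, axis=1)
    n_obs_ge = abs_obs.size - np.searchsorted(obs_sorted, thresholds, side="left")
    false_counts = np.empty((abs_perm.shape[0], thresholds.size))
    for i in range(abs_perm.shape[0]):
        false_counts[i] = abs_perm.shape[1] - np.searchsorted(
            perm_sorted[i], thresholds, side="left")
    median_false = np.median(false_counts, axis=0)
    fdr = median_false / np.maximum(n_obs_ge, 1)

    ok = fdr <= target_fdr
    if ok.any():
        # largest significant set = the most permissive threshold meeting target
        theta = thresholds[np.where(ok)[0][-1]]
    else:
        theta = math.inf
    significant = np.zeros(X.shape[0], dtype=bool)
    significant[testable] = np.abs(d_obs[testable]) >= theta

    table = pd.DataFrame({
        "effect": eff, "d_stat": d_obs, "p_plain": p_plain,
        "n_used": n_used, "significant": significant}, index=ids)
    curve = pd.DataFrame({"threshold": thresholds, "n_observed": n_obs_ge,
                          "median_false": median_false, "fdr": fdr})
    return PermutationFdrResult(table, float(theta), curve,
                                n_permutations=perm_d.shape[0],
                                exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

@dataclass
class QValueResult:
    table: pd.DataFrame    # p_value, q_value (input order)
    pi0: float


def storey_qvalues(p_values, pi0: float | None = None) -> QValueResult:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated from pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on
    the grid lambda = 0.05..0.95, smoothed with a cubic fit and evaluated at
    the largest lambda, clipped to (0, 1].  With fewer than 100 p-values the
    conservative pi0 = 1 is used.  q_(i) = min_{j>=i} pi0 * m * p_(j) / j.
    """
    idx = p_values.index if isinstance(p_values, pd.Series) else None
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
            coef = np.polyfit(lam, pi0_lam, 3)
            pi0 = float(np.polyval(coef, lam[-1]))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")

    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_ranked = pi0 * m * ranked / np.arange(1, m + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty(m)
    q[order] = q_ranked
    table = pd.DataFrame({"p_value": p, "q_value": q}, index=idx)
    return QValueResult(table, pi0)
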