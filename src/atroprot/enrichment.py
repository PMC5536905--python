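"""One-dimensional annotation enrichment of ratio distributions.

For every annotation term the per-protein values (e.g. log2 den/ctrl at one
time point) of term members are compared with non-members by a two-sided
Mann-Whitney U test.  The enrichment score is the rank-biserial form
s = 2 U / (n_in n_out) - 1 in [-1, 1] (positive when members rank high),
so it is invariant under monotone transforms of the values.  Benjamini-
Hochberg adjustment is applied across terms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .tables import AnnotationSet, TimeProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 10


def enrichment_1d(values: pd.Series, terms: AnnotationSet,
                  min_size: int = DEFAULT_MIN_SIZE) -> pd.DataFrame:
    """Rank-based 1D enrichment of every term against the background.

    Proteins without a value are excluded from both the member and the
    background set.  Terms with fewer than ``min_size`` members carrying
    values are skipped (logged).
    """
    values = values.dropna()
    universe = set(values.index)
    rows = []
    n_skipped = 0
    for tid in sorted(terms.terms):
        members = terms.terms[tid] & universe
        n_in = len(members)
        n_out = len(universe) - n_in
        if n_in < min_size or n_out < 1:
            n_skipped += 1
            continue
        member_mask = values.index.isin(members)
        x = values[member_mask].to_numpy()
        y = values[~member_mask].to_numpy()
        u, p = mannwhitneyu(x, y, alternative="two-sided")
        s = 2.0 * u / (n_in * n_out) - 1.0
        rows.append((tid, terms.names.get(tid, tid), n_in, n_out, s, p))
    if n_skipped:
        logger.info("enrichment_1d: skipped %d terms below min_size=%d",
                    n_skipped, min_size)
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "n_in", "n_out",
                                      "score", "p_value"]).set_index("term_id")
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["direction"] = np.where(out["score"] > 0, "up", "down")
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
        out["direction"] = pd.Series(dtype=object)
    return out


def enrichment_over_time(profiles: TimeProfileMatrix, terms: AnnotationSet,
                         min_size: int = DEFAULT_MIN_SIZE
                         ) -> tuple[dict[float, pd.DataFrame], pd.DataFrame]:
    """Run 1D enrichment per time point; also return the term x time score matrix."""
    per_time = {}
    scores = {}
    for t in profiles.times:
        res = enrichment_1d(profiles.values[t], terms, min_size=min_size)
        per_time[t] = res
        scores[t] = res["score"]
    score_matrix = pd.DataFrame(scores)
    return per_time, score_matrix
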