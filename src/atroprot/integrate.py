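"""Cross-data-set integration: expression vs synthesis sectors, mRNA
correlation and sample-level QC.

The 3x3 sector classification crosses a protein's expression call
(down / unchanged / up, from the permutation-FDR test of log2 den/ctrl)
with its label-incorporation call at the same time point.  Sector indices
run row-major: expression state varies slowest (down -> up) and the
incorporation state fastest, so the "stabilized" class -- expression up
with unchanged incorporation -- is sector 8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

_STATES = ("down", "unchanged", "up")
#: sector = 3 * index(expression_state) + index(incorporation_state) + 1
STABILIZED_SECTOR = 3 * _STATES.index("up") + _STATES.index("unchanged") + 1


def _state(table: pd.DataFrame, sig_col: str = "significant") -> pd.Series:
    sig = table[sig_col].astype(bool)
    eff = table["effect"]
    return pd.Series(np.where(sig & (eff > 0), "up",
                     np.where(sig & (eff < 0), "down", "unchanged")),
                     index=table.index)


def classify_sectors(expr_tests: pd.DataFrame, incorp_tests: pd.DataFrame,
                     incorp_sig_col: str = "q_significant") -> pd.DataFrame:
    """Assign every jointly quantified protein to one of nine sectors.

    Both inputs are id-indexed test tables with ``effect`` and a boolean
    significance column (``significant`` for expression; for incorporation
    the per-time q-value call by default).  Proteins present in only one
    table are excluded (counted in the log).
    """
    shared = expr_tests.index.intersection(incorp_tests.index)
    n_excl = len(expr_tests.index.symmetric_difference(incorp_tests.index))
    if n_excl:
        logger.info("classify_sectors: %d proteins present in only one data set",
                    n_excl)
    e_state = _state(expr_tests.loc[shared])
    i_state = _state(incorp_tests.loc[shared],
                     incorp_sig_col if incorp_sig_col in incorp_tests.columns
                     else "significant")
    sector = (3 * e_state.map(_STATES.index) + i_state.map(_STATES.index) + 1)
    return pd.DataFrame({"expression_state": e_state,
                         "incorporation_state": i_state,
                         "sector": sector.astype(int)}, index=shared)


def profile_correlation(profiles_a: pd.Series, profiles_b: pd.Series
                        ) -> tuple[float, int]:
    """Pearson r over the id intersection; returns (r, n_overlap).

    With fewer than three overlapping ids the correlation is not computed
    (returns (nan, n)).
    """
    shared = profiles_a.dropna().index.intersection(profiles_b.dropna().index)
    n = len(shared)
    if n < 3:
        return float("nan"), n
    r, _ = pearsonr(profiles_a.loc[shared], profiles_b.loc[shared])
    return float(r), n


@dataclass
class QcSummary:
    correlation: pd.DataFrame       # samples x samples Pearson
    linkage_order: list[str]        # average-linkage leaf order
    pca: pd.DataFrame               # samples x (PC1, PC2)
    explained_variance_ratio: tuple[float, float]


def qc_summary(values: pd.DataFrame) -> QcSummary:
    """Sample-level QC on a proteins x samples log2-ratio matrix.

    Pairwise Pearson correlation on complete pairs; average-linkage
    clustering of the Euclidean distances between correlation rows; PCA of
    the samples on mean-centred complete protein rows (first two components,
    no variance scaling).
    """
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    corr = values.corr(method="pearson", min_periods=2)
    Z = linkage(pdist(corr.to_numpy(), metric="euclidean"), method="average")
    order = [corr.index[i] for i in leaves_list(Z)]

    complete = values.dropna()
    X = complete.to_numpy(dtype=float).T            # samples x proteins
    X = X - X.mean(axis=0, keepdims=True)           # centre each protein
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    if n_comp < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
        evr = (float(pca.explained_variance_ratio_[0]), 0.0)
    else:
        evr = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
    pc = pd.DataFrame(coords[:, :2], index=values.columns, columns=["PC1", "PC2"])
    return QcSummary(corr, order, pc, evr)
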