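"""Diglycine-remnant (ubiquitination) site analysis.

Site-level den/ctrl ratios confound ubiquitination-occupancy changes with
protein-abundance changes; normalization subtracts the protein's mean log2
ratio at the matched time point (site and protein measurements come from
different digestion workflows, so replicates are not paired).  Regulated
sites require both permutation-FDR significance and a fold change beyond
the cut (1.5 by default), the fold criterion being applied to the raw site
ratio with the normalized value reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .stats import DEFAULT_S0, permutation_fdr
from .tables import SiteQuantTable, TimeProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_FOLD_CUT = 1.5


@dataclass
class NormalizedSites:
    """Per-site raw and protein-normalized log2 ratios per sample."""

    sites: pd.DataFrame           # site metadata (protein_id, residue_position, ...)
    raw: pd.DataFrame             # sites x samples, log2(den/ctrl)
    normalized: pd.DataFrame      # site - protein profile at matched time
    protein_quantified: pd.DataFrame   # bool, sites x samples
    orphans: pd.Index             # sites whose protein has no profile


def normalize_site_ratios(sites: SiteQuantTable,
                          profiles: TimeProfileMatrix) -> NormalizedSites:
    """Subtract the protein's mean log2 ratio at each matched time point.

    Where the protein is unquantified at that time the raw value is kept and
    flagged ``protein_quantified=False``.  Sites referencing proteins absent
    from the profile matrix are listed as orphans (excluded from normalized
    statistics but kept in the raw table).
    """
    meta = sites.sites
    design = sites.design.frame.set_index("sample_id")
    known = meta["protein_id"].isin(profiles.values.index)
    orphans = meta.index[~known]
    if len(orphans):
        logger.warning("normalize_site_ratios: %d orphan sites (unknown protein)",
                       len(orphans))
    raw = sites.log2_ratio
    normalized = raw.copy()
    quantified = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    for sid in raw.columns:
        t = design.loc[sid, "time_day"]
        if t not in profiles.values.columns:
            continue
        prot = profiles.values[t].reindex(meta["protein_id"]).to_numpy()
        has = ~np.isnan(prot) & known.to_numpy()
        normalized[sid] = np.where(has, raw[sid].to_numpy() - prot, raw[sid].to_numpy())
        quantified[sid] = has
    return NormalizedSites(meta, raw, normalized, quantified, orphans)


def regulated_sites(values: pd.DataFrame, design, *, s0: float = DEFAULT_S0,
                    target_fdr: float = 0.05, fold_cut: float = DEFAULT_FOLD_CUT,
                    n_perm=250, seed: int | None = None
                    ) -> dict[float, pd.DataFrame]:
    """Per-time one-sample moderated tests of site log2 ratios against zero.

    *values* is sites x samples (raw or normalized); *design* maps samples to
    time points and replicates.  A site is flagged regulated at a time point
    when it is permutation-FDR significant AND its |mean log2 ratio| exceeds
    log2(fold_cut).
    """
    frame = design.frame if hasattr(design, "frame") else design
    log_cut = np.log2(fold_cut)
    out = {}
    for t in sorted(frame["time_day"].unique()):
        cols = list(frame.loc[frame["time_day"] == t, "sample_id"])
        cols = [c for c in cols if c in values.columns]
        if not cols:
            continue
        res = permutation_fdr(values[cols], labels=None, s0=s0,
                              target_fdr=target_fdr, n_perm=n_perm, seed=seed)
        tab = res.table.copy()
        tab["fold_ok"] = tab["effect"].abs() > log_cut
        tab["regulated"] = tab["significant"] & tab["fold_ok"]
        out[float(t)] = tab
    return out


def sites_per_protein(sites: SiteQuantTable) -> tuple[pd.Series, dict]:
    """Exact histogram of diglycine sites per protein, with summary stats."""
    counts = sites.sites.groupby("protein_id").size()
    hist = counts.value_counts().sort_index()
    hist.index.name = "sites_per_protein"
    hist.name = "n_proteins"
    summary = {"n_proteins": int(counts.size), "n_sites": int(counts.sum()),
               "max": int(counts.max()), "median": float(counts.median())}
    return hist, summary


def positional_gradient(positions, regulated, protein_length: int
                        ) -> tuple[float, float]:
    """Test whether regulated sites sit closer to the C-terminus.

    Relative position x = residue_position / protein_length in (0, 1]; the
    one-sided Mann-Whitney alternative is "regulated sites have larger x".
    Returns ``(p_value, effect)`` with the signed rank-biserial effect size
    (positive = regulated toward the C-terminus).  Requires >= 5 sites and
    at least one site in each group; otherwise ``(nan, nan)``.
    """
    pos = np.asarray(positions, dtype=float)
    reg = np.asarray(regulated, dtype=bool)
    if pos.size < 5 or reg.all() or not reg.any():
        return float("nan"), float("nan")
    if np.any(pos < 1) or np.any(pos > protein_length):
        raise ValueError("positions must lie in [1, protein_length]")
    x = pos / float(protein_length)
    u, p = mannwhitneyu(x[reg], x[~reg], alternative="greater")
    effect = 2.0 * u / (reg.sum() * (~reg).sum()) - 1.0
    return float(p), float(effect)
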