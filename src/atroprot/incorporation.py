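"""Pulsed-SILAC analysis: labelling fractions, AUC and differential synthesis.

During the pulse the diet supplies heavy lysine, so newly made protein is
heavy and the labelled fraction is f = (H/L)/(H/L + 1).  Per-protein
synthesis over the time course is summarized by the trapezoidal area under
the incorporation curve (anchored at (0, 0) by default: labelling starts at
the diet switch).  Differential incorporation between conditions is tested
per time point on the log2 ratio of H/L ratios (one-sample moderated test
against zero) with Storey q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import PairingError
from .stats import DEFAULT_S0, permutation_fdr, storey_qvalues
from .tables import ProteinQuantTable, SampleDesign

logger = logging.getLogger(__name__)


def labelling_fraction(hl_ratio):
    """f = r/(r+1) for H/L ratio r >= 0 (elementwise)."""
    r = np.asarray(hl_ratio, dtype=float)
    if np.any(r[~np.isnan(r)] < 0):
        raise ValueError("H/L ratio must be non-negative")
    out = r / (r + 1.0)
    return out.item() if np.isscalar(hl_ratio) else out


def fraction_to_ratio(f):
    """Inverse transform r = f/(1-f) for f in [0, 1)."""
    f = np.asarray(f, dtype=float)
    if np.any(f[~np.isnan(f)] < 0) or np.any(f[~np.isnan(f)] >= 1):
        raise ValueError("fraction must lie in [0, 1)")
    out = f / (1.0 - f)
    return out.item() if out.ndim == 0 else out


def incorporation_auc(times, fractions, anchor_zero: bool = True) -> float:
    """Trapezoidal area under the incorporation-time profile.

    With ``anchor_zero`` the point (0, 0) is prepended (no label before the
    diet switch).  Units: fraction x days.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size != f.size or t.size < 2:
        raise ValueError("need >= 2 matching (time, fraction) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if anchor_zero and t[0] > 0:
        t = np.concatenate([[0.0], t])
        f = np.concatenate([[0.0], f])
    return float(np.trapezoid(f, t))


def fit_one_pool_rate(times, fractions) -> float:
    """Least-squares rate constant of f(t) = 1 - exp(-k t), per day.

    Fit on the linearized form -ln(1 - f) = k t through the origin:
    k = sum(t * y) / sum(t^2).
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size != f.size or t.size < 2:
        raise ValueError("need >= 2 matching points")
    if np.any(f >= 1.0) or np.any(f < 0.0):
        raise ValueError("fractions must lie in [0, 1)")
    y = -np.log1p(-f)
    return float(np.sum(t * y) / np.sum(t * t))


@dataclass
class IncorporationProfiles:
    """Replicate-averaged labelled fraction per time and condition, with AUC."""

    fractions: pd.DataFrame     # proteins x MultiIndex (condition, time_day)
    auc: pd.DataFrame           # proteins x condition
    n_times_observed: pd.DataFrame


def incorporation_profiles(table: ProteinQuantTable, anchor_zero: bool = True,
                           min_times_for_auc: int = 2) -> IncorporationProfiles:
    """Per-protein labelling fractions f(t) and AUC per condition.

    Proteins observed at fewer than ``min_times_for_auc`` time points in a
    condition get a missing AUC (they are excluded from AUC comparison but
    retained in per-time tests).
    """
    design = table.design.frame
    frac_cols = {}
    for (cond, t), grp in design.groupby(["condition", "time_day"]):
        hl = table.hl_ratio[list(grp["sample_id"])]
        frac = hl / (hl + 1.0)      # labelling_fraction, frame-shaped
        frac_cols[(cond, float(t))] = frac.mean(axis=1, skipna=True)
    fractions = pd.DataFrame(frac_cols)
    fractions.columns = pd.MultiIndex.from_tuples(fractions.columns,
                                                  names=["condition", "time_day"])
    aucs = {}
    n_obs = {}
    for cond in fractions.columns.get_level_values("condition").unique():
        sub = fractions[cond]
        times = np.array(sorted(sub.columns))
        sub = sub[times]
        n_obs[cond] = sub.notna().sum(axis=1)
        vals = []
        for _, row in sub.iterrows():
            mask = row.notna().to_numpy()
            if mask.sum() < max(min_times_for_auc, 2):
                vals.append(np.nan)
            else:
                vals.append(incorporation_auc(times[mask], row.to_numpy()[mask],
                                              anchor_zero=anchor_zero))
        aucs[cond] = vals
    auc = pd.DataFrame(aucs, index=fractions.index)
    return IncorporationProfiles(fractions, auc, pd.DataFrame(n_obs))


def differential_incorporation(table: ProteinQuantTable, *,
                               s0: float = DEFAULT_S0, alpha: float = 0.05,
                               n_perm=250, seed: int | None = None,
                               anchor_zero: bool = True) -> dict:
    """Per-time one-sample tests of log2[(H/L)_den / (H/L)_ctrl] vs zero.

    Replicates are paired by index.  Returns per-time result tables with
    moderated d, permutation significance and Storey q-values, plus the
    per-protein AUC difference (den - ctrl).
    """
    design = table.design.frame
    with np.errstate(divide="ignore", invalid="ignore"):
        log_hl = np.log2(table.hl_ratio)
    results = {}
    for t in sorted(design["time_day"].unique()):
        ctrl = design[(design["time_day"] == t) & (design["condition"] == "control")]
        den = design[(design["time_day"] == t) & (design["condition"] == "denervated")]
        c_by_rep = dict(zip(ctrl["replicate"], ctrl["sample_id"]))
        d_by_rep = dict(zip(den["replicate"], den["sample_id"]))
        if set(c_by_rep) != set(d_by_rep):
            raise PairingError(f"pulse day {t}: replicates cannot be paired")
        reps = sorted(c_by_rep)
        ratios = pd.DataFrame(
            {r: log_hl[d_by_rep[r]] - log_hl[c_by_rep[r]] for r in reps})
        res = permutation_fdr(ratios, labels=None, s0=s0, target_fdr=alpha,
                              n_perm=n_perm, seed=seed)
        tab = res.table.copy()
        testable = tab["p_plain"].notna()
        qv = np.full(len(tab), np.nan)
        if testable.any():
            qres = storey_qvalues(tab.loc[testable, "p_plain"])
            qv[testable.to_numpy()] = qres.table["q_value"].to_numpy()
        tab["q_value"] = qv
        tab["q_significant"] = tab["q_value"] < alpha
        results[float(t)] = tab

    profiles = incorporation_profiles(table, anchor_zero=anchor_zero)
    auc_diff = None
    if {"control", "denervated"} <= set(profiles.auc.columns):
        auc_diff = profiles.auc["denervated"] - profiles.auc["control"]
    return {"per_time": results, "profiles": profiles, "auc_diff": auc_diff}
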