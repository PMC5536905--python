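"""Spike-in SILAC quantification: ratio-of-ratios against the heavy standard.

Every light sample shares the same fully labelled heavy spike-in, so the
den/ctrl fold change of a protein is the difference of its per-sample
log2(L/H) values -- the standard cancels.  Replicates are paired by index
(each animal supplies a control and a denervated leg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import ProteinQuantTable, SampleDesign, TimeProfileMatrix

logger = logging.getLogger(__name__)


class PairingError(ValueError):
    """Control and denervated replicate sets cannot be paired."""


@dataclass
class NormalizedRatioTable:
    """Median-centred log2(L/H) per sample, with the removed offsets."""

    log2_lh: pd.DataFrame       # proteins x samples
    offsets: pd.Series          # per-sample median removed
    design: SampleDesign


def normalize_sample_ratios(table: ProteinQuantTable) -> NormalizedRatioTable:
    """Subtract the per-sample median log2(L/H) (SILAC loading normalization).

    After centring, the per-sample median of normalized log2(L/H) over the
    proteins quantified in that sample is zero.
    """
    lh = table.log2_lh()
    offsets = lh.median(axis=0, skipna=True)
    empty = offsets.index[lh.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"sample(s) with zero quantified proteins: {list(empty)}")
    return NormalizedRatioTable(lh - offsets, offsets, table.design)


def ratio_of_ratios(ctrl: Sequence[float], den: Sequence[float]) -> np.ndarray:
    """log2 fold change den/ctrl per replicate pair.

    Both arguments are per-replicate log2(L/H) values against the common
    heavy standard; pairing is positional (replicate index).
    """
    ctrl = np.asarray(ctrl, dtype=float)
    den = np.asarray(den, dtype=float)
    if ctrl.shape != den.shape:
        raise PairingError(
            f"unmatched replicate counts: {ctrl.shape} vs {den.shape}")
    return den - ctrl


def fold_change_table(norm: NormalizedRatioTable) -> pd.DataFrame:
    """Per-protein log2(den/ctrl) per (time, replicate), paired by replicate.

    Columns are a MultiIndex (time_day, replicate).  A pair is missing when
    either side is unquantified.
    """
    design = norm.design.frame
    cols = {}
    for t in sorted(design["time_day"].unique()):
        ctrl = design[(design["time_day"] == t) & (design["condition"] == "control")]
        den = design[(design["time_day"] == t) & (design["condition"] == "denervated")]
        ctrl_by_rep = dict(zip(ctrl["replicate"], ctrl["sample_id"]))
        den_by_rep = dict(zip(den["replicate"], den["sample_id"]))
        reps = sorted(set(ctrl_by_rep) & set(den_by_rep))
        if set(ctrl_by_rep) != set(den_by_rep):
            raise PairingError(
                f"day {t}: control replicates {sorted(ctrl_by_rep)} vs "
                f"denervated {sorted(den_by_rep)} cannot be paired by index")
        for r in reps:
            cols[(t, r)] = norm.log2_lh[den_by_rep[r]] - norm.log2_lh[ctrl_by_rep[r]]
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["time_day", "replicate"])
    return out


def build_time_profiles(fold_changes: pd.DataFrame,
                        design: SampleDesign | None = None) -> TimeProfileMatrix:
    """Average replicate fold changes into a proteins x time matrix.

    Cells supported by fewer than two replicate values are kept but flagged
    low-evidence (they are excluded from hypothesis tests downstream).
    """
    means = fold_changes.T.groupby(level="time_day").mean().T
    n_obs = fold_changes.notna().T.groupby(level="time_day").sum().T
    means = means[sorted(means.columns)]
    n_obs = n_obs[means.columns]
    return TimeProfileMatrix(means, n_obs)


def myhc_composition(peptide_intensities: Mapping[str, Sequence[float]]
                     ) -> dict[str, float]:
    """Label-free myosin heavy chain composition from unique peptides.

    The fraction of isoform *i* is the summed intensity of its unique
    peptides over the total across isoforms; the result is a probability
    vector over isoforms.
    """
    sums = {iso: float(np.sum(np.asarray(v, dtype=float)))
            for iso, v in peptide_intensities.items()}
    if any(v < 0 for v in sums.values()):
        raise ValueError("peptide intensities must be non-negative")
    total = sum(sums.values())
    if total <= 0:
        raise ValueError("all-zero peptide intensities")
    return {iso: v / total for iso, v in sums.items()}
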