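"""Atrogene-likeness scoring with shuffled-negative random-forest ensembles.

Two curated training classes (Class 1: upregulated upon denervation;
Class 2: downregulated) are each discriminated from a negative class built
by shuffling the quantified profiles: every negative example samples each
time-point column independently from that column's empirical distribution,
destroying temporal correlation while preserving the per-time marginals --
exactly the structure a profile classifier must learn.

Because a single shuffled negative set could bias the classifier by chance,
the procedure trains an ensemble of repeats (50 by default), each with fresh
negatives and with the number of candidate features per split (mtry) tuned
by cross-validated Cohen's kappa; class probabilities are averaged over the
repeats.  The Delta Score is P(Class 1) - P(Class 2), and candidates are
proteins whose averaged probability strictly exceeds the threshold (0.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

DEFAULT_N_REPEATS = 50
DEFAULT_N_TREES = 500
DEFAULT_CV_FOLDS = 5
DEFAULT_THRESHOLD = 0.7


class ConfigError(ValueError):
    pass


@dataclass
class TrainingClasses:
    """Curated exemplar sets with complete feature vectors.

    Features are log2(den/ctrl) at the expression time points.
    """

    class1_ids: set[str]
    class2_ids: set[str]

    def __post_init__(self) -> None:
        overlap = self.class1_ids & self.class2_ids
        if overlap:
            raise ConfigError(f"training classes overlap: {sorted(overlap)[:3]}")


def prepare_features(profiles: pd.DataFrame, min_points: int = 3) -> pd.DataFrame:
    """Complete feature matrix; rows with >= min_points observed are kept.

    A single missing time point is filled with the nearest observed value
    (flagged in the ``imputed`` attribute-free companion column is omitted;
    callers can compare against ``profiles``); rows with more missing data
    are dropped.
    """
    n_obs = profiles.notna().sum(axis=1)
    keep = profiles[n_obs >= min_points]
    n_dropped = len(profiles) - len(keep)
    if n_dropped:
        logger.info("prepare_features: dropped %d proteins with <%d time points",
                    n_dropped, min_points)
    filled = keep.ffill(axis=1).bfill(axis=1)
    return filled


def shuffled_negatives(features: pd.DataFrame | np.ndarray, n_neg: int,
                       rng: np.random.Generator | int | None = None,
                       mode: str = "column_resample") -> np.ndarray:
    """Negative-class examples by column-wise independent resampling.

    ``mode="column_resample"`` (default) draws, independently per time-point
    column, values from that column's empirical distribution;
    ``mode="row_permute"`` instead permutes each column of the source matrix
    (an alternative reading of "shuffling the data set").
    """
    if n_neg <= 0:
        raise ConfigError("n_neg must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    n, p = X.shape
    if mode == "column_resample":
        cols = [X[rng.integers(0, n, size=n_neg), j] for j in range(p)]
        return np.column_stack(cols)
    if mode == "row_permute":
        out = X.copy()
        for j in range(p):
            out[:, j] = X[rng.permutation(n), j]
        return out[rng.integers(0, n, size=n_neg)]
    raise ConfigError(f"unknown shuffle mode {mode!r}")


def _tune_mtry(X: np.ndarray, y: np.ndarray, n_trees: int, folds: int,
               rng: np.random.Generator) -> int:
    """Grid-search mtry over 1..n_features by CV Cohen's kappa at 0.5 votes."""
    best_mtry, best_kappa = 1, -np.inf
    for mtry in range(1, X.shape[1] + 1):
        kappas = []
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for train, test in skf.split(X, y):
            if len(np.unique(y[train])) < 2:   # degenerate fold; re-stratify
                logger.info("degenerate CV fold encountered; skipping fold")
                continue
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features=mtry,
                random_state=int(rng.integers(2 ** 31)), n_jobs=1)
            clf.fit(X[train], y[train])
            proba = clf.predict_proba(X[test])[:, list(clf.classes_).index(1)]
            kappas.append(cohen_kappa_score(y[test], (proba >= 0.5).astype(int)))
        kappa = float(np.mean(kappas)) if kappas else -np.inf
        if kappa > best_kappa:
            best_kappa, best_mtry = kappa, mtry
    return best_mtry


@dataclass
class AtrogeneScores:
    """Averaged class probabilities, Delta Score and candidate calls."""

    table: pd.DataFrame    # p_class1, p_class2, delta, is_training_1, is_training_2
    training_insample_mean: dict[int, float]
    n_repeats: int


def train_scoring_ensemble(classes: TrainingClasses, features: pd.DataFrame,
                           n_repeats: int = DEFAULT_N_REPEATS,
                           n_trees: int = DEFAULT_N_TREES,
                           cv_folds: int = DEFAULT_CV_FOLDS,
                           seed: int | None = None,
                           shuffle_mode: str = "column_resample"
                           ) -> AtrogeneScores:
    """Train the shuffled-negative ensembles and score every protein.

    For each repeat and each class k: fresh negatives are drawn, mtry is
    tuned by ``cv_folds``-fold Cohen's kappa, a forest is trained on
    (class-k exemplars vs negatives) and all proteins are scored with
    P(class k).  Final probabilities are the mean over repeats.
    """
    for k, ids in ((1, classes.class1_ids), (2, classes.class2_ids)):
        missing = ids - set(features.index)
        if missing:
            raise ConfigError(f"class {k} exemplars lack features: {sorted(missing)[:3]}")
        if len(ids) < 5:
            raise ConfigError(f"class {k} needs >= 5 exemplars, has {len(ids)}")

    X_all = features.to_numpy(dtype=float)
    master = np.random.SeedSequence(seed)
    sums = {1: np.zeros(len(features)), 2: np.zeros(len(features))}
    for rep_seq in master.spawn(n_repeats):
        rng = np.random.default_rng(rep_seq)
        for k, ids in ((1, classes.class1_ids), (2, classes.class2_ids)):
            pos = features.loc[sorted(ids)].to_numpy(dtype=float)
            neg = shuffled_negatives(features, n_neg=len(pos), rng=rng,
                                     mode=shuffle_mode)
            X = np.vstack([pos, neg])
            y = np.concatenate([np.ones(len(pos), dtype=int),
                                np.zeros(len(neg), dtype=int)])
            folds = min(cv_folds, len(pos))
            mtry = _tune_mtry(X, y, n_trees, folds, rng)
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features=mtry,
                random_state=int(rng.integers(2 ** 31)), n_jobs=1)
            clf.fit(X, y)
            sums[k] += clf.predict_proba(X_all)[:, list(clf.classes_).index(1)]

    p1 = sums[1] / n_repeats
    p2 = sums[2] / n_repeats
    table = pd.DataFrame({
        "p_class1": p1, "p_class2": p2, "delta": p1 - p2,
        "is_training_1": features.index.isin(classes.class1_ids),
        "is_training_2": features.index.isin(classes.class2_ids),
    }, index=features.index)
    insample = {
        1: float(table.loc[table["is_training_1"], "p_class1"].mean()),
        2: float(table.loc[table["is_training_2"], "p_class2"].mean()),
    }
    return AtrogeneScores(table, insample, n_repeats)


def oof_training_scores(classes: TrainingClasses, features: pd.DataFrame,
                        n_splits: int = 3, n_repeats: int = 5,
                        n_trees: int = 100, seed: int | None = None
                        ) -> dict[int, float]:
    """Out-of-fold probability of the training exemplars on their own class.

    Complements the in-sample average (the conventional summary): exemplars are
    split into folds, the ensemble is retrained without each fold and the
    held-out exemplars are scored.  Lightweight settings by default.
    """
    out = {}
    rng = np.random.default_rng(seed)
    for k, ids in ((1, sorted(classes.class1_ids)), (2, sorted(classes.class2_ids))):
        ids = list(ids)
        perm = rng.permutation(len(ids))
        folds = np.array_split(perm, n_splits)
        probs = []
        for fold in folds:
            held = {ids[i] for i in fold}
            rest = set(ids) - held
            if len(rest) < 5:
                continue
            sub = TrainingClasses(rest if k == 1 else set(classes.class1_ids),
                                  rest if k == 2 else set(classes.class2_ids))
            scores = train_scoring_ensemble(sub, features, n_repeats=n_repeats,
                                            n_trees=n_trees, cv_folds=3,
                                            seed=int(rng.integers(2 ** 31)))
            col = "p_class1" if k == 1 else "p_class2"
            probs.extend(scores.table.loc[sorted(held), col].tolist())
        out[k] = float(np.mean(probs)) if probs else np.nan
    return out


def call_candidates(scores: AtrogeneScores,
                    threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Candidate atrogenes: averaged probability strictly above the threshold.

    Direction "up" for p_class1 > threshold, "down" for p_class2 > threshold.
    """
    t = scores.table
    up = t["p_class1"] > threshold
    down = t["p_class2"] > threshold
    out = t[up | down].copy()
    out["direction"] = np.where(out["p_class1"] > threshold, "up", "down")
    return out
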