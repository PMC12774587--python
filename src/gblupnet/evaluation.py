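"""Validation design and predictive-ability metrics.

The test set is defined by birth year (the youngest generations); the
remaining pool is split 50 times into training and validation sets, either as
10-fold cross-validation repeated 5 times (default) or as 50 random
80/20 fraction splits.  Predictive ability is the Pearson correlation r
between predictions and the pre-corrected test phenotypes, summarized either
as the mean r over splits (splits-average) or as the r of the per-animal
mean prediction across splits (averaged-predictions, a bagging-style
ensemble).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedKFold, ShuffleSplit


@dataclass
class SplitScheme:
    """Fixed test set plus repeated train/validation partitions of the pool."""

    pool_ids: list
    test_ids: list
    splits: list  # list of (train_ids, val_ids)
    mode: str
    seed: int

    @property
    def n_splits(self) -> int:
        return len(self.splits)


@dataclass
class SplitPredictions:
    """Per-split prediction vectors for one fixed test set (n_splits x n_test)."""

    values: np.ndarray
    test_ids: list
    model_tag: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.test_ids):
            raise ValueError("prediction columns must align with test ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("split predictions contain missing entries")


def make_splits(
    phenotypes: pd.DataFrame,
    mode: str = "kfold_repeated",
    seed: int = 0,
    test_years: tuple | None = None,
    birth_year_col: str = "birth_year",
    n_folds: int = 10,
    n_repeats: int = 5,
    val_fraction: float = 0.2,
    n_fraction_splits: int = 50,
) -> SplitScheme:
    """Partition animals by birth year and build the 50 train/validation splits.

    ``test_years`` defaults to the two most recent birth years present.
    """
    if birth_year_col not in phenotypes.columns:
        raise ValueError(f"phenotype table lacks a {birth_year_col!r} column")
    years = phenotypes[birth_year_col]
    if test_years is None:
        uniq = np.sort(years.unique())
        test_years = tuple(uniq[-2:]) if len(uniq) > 2 else (uniq[-1],)
    is_test = years.isin(test_years).to_numpy()
    test_ids = list(phenotypes.index[is_test])
    pool_ids = list(phenotypes.index[~is_test])
    if not test_ids:
        raise ValueError(f"no animals born in test years {test_years}")

    pool = np.asarray(pool_ids, dtype=object)
    splits = []
    if mode == "kfold_repeated":
        if len(pool) < n_folds:
            raise ValueError(f"k-fold mode needs at least {n_folds} pool animals")
        kf = RepeatedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
        for train_i, val_i in kf.split(pool):
            splits.append((list(pool[train_i]), list(pool[val_i])))
    elif mode == "fraction":
        ss = ShuffleSplit(n_splits=n_fraction_splits, test_size=val_fraction, random_state=seed)
        for train_i, val_i in ss.split(pool):
            splits.append((list(pool[train_i]), list(pool[val_i])))
    else:
        raise ValueError("mode must be 'kfold_repeated' or 'fraction'")
    return SplitScheme(pool_ids=pool_ids, test_ids=test_ids, splits=splits, mode=mode, seed=seed)


def _pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def splits_average(preds: SplitPredictions, y_test) -> tuple[float, float]:
    """Mean and sample SD of the per-split Pearson r against test phenotypes.

    Splits with zero-variance predictions have undefined r; they are excluded
    with a warning rather than imputed.
    """
    y_test = np.asarray(y_test, dtype=float)
    if preds.values.shape[0] < 1:
        raise ValueError("need at least one split")
    rs = np.array([_pearson(row, y_test) for row in preds.values])
    bad = np.isnan(rs)
    if bad.any():
        warnings.warn(f"excluding {bad.sum()} split(s) with undefined correlation")
    rs = rs[~bad]
    if rs.size == 0:
        raise ValueError("correlation undefined in every split")
    sd = float(rs.std(ddof=1)) if rs.size > 1 else 0.0
    return float(rs.mean()), sd


def averaged_predictions(preds: SplitPredictions, y_test) -> float:
    """r between the per-animal mean prediction over splits and test phenotypes."""
    y_test = np.asarray(y_test, dtype=float)
    avg = preds.values.mean(axis=0)
    r = _pearson(avg, y_test)
    if np.isnan(r):
        raise ValueError("averaged prediction vector is constant; r undefined")
    return r


def se_of_r(r: float, n_test: int) -> float:
    """Standard error of a Pearson correlation: sqrt((1 - r^2) / (n_test - 2))."""
    if n_test <= 2:
        raise ValueError("se_of_r requires n_test > 2")
    if abs(r) >= 1:
        raise ValueError("se_of_r requires |r| < 1")
    return float(np.sqrt((1.0 - r**2) / (n_test - 2)))


def relative_improvement(r_new: float, r_base: float) -> float:
    """Percent change of predictive ability relative to a baseline r."""
    if r_base == 0:
        raise ValueError("baseline correlation is zero")
    return 100.0 * (r_new / r_base - 1.0)
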