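"""Stable age-associated feature selection by repeated LASSO.

An L1-penalized linear regression of age on features is fitted once per seed
(default seeds 1..100); within each run the penalty is chosen by 10-fold
cross-validation (CV-minimum lambda) with the fold assignment controlled by
that run's seed. A feature counts as selected in a run when its coefficient
is nonzero at the chosen penalty, and is kept overall when selected in at
least ``threshold_fraction`` of runs (default one half, inclusive; a
``strict`` flag switches to a strictly-greater cut). Features enter the
solver unstandardized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted, check_X_y

from .io import FeatureTable, ValidationError


class LassoStabilitySelector(SelectorMixin, BaseEstimator):
    """Select features by LASSO selection frequency across seeded CV runs.

    Parameters
    ----------
    n_seeds : int, default 100
        Number of repeated fits; run ``s`` uses seed ``s`` (1-based).
    threshold_fraction : float in (0, 1], default 0.5
        Minimum fraction of runs a feature must be selected in.
    strict : bool, default False
        If True, require strictly more than the threshold count.
    cv_folds : int, default 10
        Folds for the per-run lambda search.

    Attributes
    ----------
    selection_counts_ : ndarray of int, shape (n_features,)
    support_ : boolean mask of the selected features
    """

    def __init__(
        self,
        n_seeds: int = 100,
        threshold_fraction: float = 0.5,
        strict: bool = False,
        cv_folds: int = 10,
    ):
        self.n_seeds = n_seeds
        self.threshold_fraction = threshold_fraction
        self.strict = strict
        self.cv_folds = cv_folds

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in (0, 1]")
        if X.shape[0] < self.cv_folds:
            raise ValueError(
                f"need at least cv_folds={self.cv_folds} samples, got {X.shape[0]}"
            )
        if np.all(X.std(axis=0) == 0):
            raise ValueError("all features are constant; nothing to select")
        counts = np.zeros(X.shape[1], dtype=int)
        for seed in range(1, self.n_seeds + 1):
            folds = KFold(n_splits=self.cv_folds, shuffle=True, random_state=seed)
            lasso = LassoCV(cv=folds, alphas=100, max_iter=10000, random_state=seed)
            lasso.fit(X, y)
            counts += lasso.coef_ != 0
        self.selection_counts_ = counts
        cut = self.threshold_fraction * self.n_seeds
        self.support_ = counts > cut if self.strict else counts >= cut
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


@dataclass
class StabilitySelectionResult:
    """Selection frequencies and the resulting stable feature set."""

    selection_counts: dict[str, int]
    selected: list[str]  # stable features, in original table order
    n_seeds: int
    threshold_fraction: float


def lasso_stability_select(
    table: FeatureTable,
    ages,
    n_seeds: int = 100,
    threshold_fraction: float = 0.5,
    strict: bool = False,
    cv_folds: int = 10,
) -> StabilitySelectionResult:
    """Run stability selection on a feature table (features x samples)."""
    sel = LassoStabilitySelector(
        n_seeds=n_seeds,
        threshold_fraction=threshold_fraction,
        strict=strict,
        cv_folds=cv_folds,
    ).fit(table.samples_array(), np.asarray(ages))
    counts = dict(zip(table.feature_ids, sel.selection_counts_.tolist()))
    selected = [f for f, keep in zip(table.feature_ids, sel.support_) if keep]
    return StabilitySelectionResult(counts, selected, n_seeds, threshold_fraction)


def apply_selection(
    table: FeatureTable, selection: StabilitySelectionResult
) -> FeatureTable:
    """Restrict a table to the stable features, preserving original order."""
    missing = [f for f in selection.selected if f not in set(table.feature_ids)]
    if missing:
        raise ValidationError(f"selected features absent from table: {missing}")
    if not selection.selected:
        raise ValidationError(
            "selection is empty; relax threshold_fraction or increase n_seeds"
        )
    keep = set(selection.selected)
    ordered = [f for f in table.feature_ids if f in keep]
    return table.select_features(ordered)
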