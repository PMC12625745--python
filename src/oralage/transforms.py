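"""The four table representations compared for age signal.

Presence/absence binarization and per-sample relative abundance are derived
from raw counts; log2 and centered log-ratio (CLR) transforms are applied to
the relative abundances with a small pseudocount (default 1e-6) to handle
zeros. CLR uses the natural log internally — centering makes the choice of
base immaterial up to a constant scale, and natural log is the
compositional-data convention.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import FeatureTable, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1e-6


def _require_kind(table: FeatureTable, kind: str) -> None:
    if table.value_kind != kind:
        raise ValidationError(
            f"expected a {kind!r} table, got value_kind={table.value_kind!r}"
        )


def binarize(table: FeatureTable) -> FeatureTable:
    """Presence/absence: 1 where the count is positive, 0 where it is zero."""
    _require_kind(table, "count")
    return FeatureTable(
        list(table.feature_ids),
        list(table.sample_ids),
        (table.values > 0).astype(float),
        "binarized",
    )


def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Per-sample proportions; an all-zero sample stays all-zero (warned)."""
    _require_kind(table, "count")
    sums = table.values.sum(axis=0)
    zero_cols = sums == 0
    if np.any(zero_cols):
        ids = [s for s, z in zip(table.sample_ids, zero_cols) if z]
        msg = f"all-zero samples left unnormalized: {ids}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    safe = np.where(zero_cols, 1.0, sums)
    return FeatureTable(
        list(table.feature_ids),
        list(table.sample_ids),
        table.values / safe,
        "relative_abundance",
    )


def log2_transform(
    table: FeatureTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> FeatureTable:
    """Elementwise log2(relative abundance + pseudocount)."""
    _require_kind(table, "relative_abundance")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return FeatureTable(
        list(table.feature_ids),
        list(table.sample_ids),
        np.log2(table.values + pseudocount),
        "log2",
    )


def clr_transform(
    table: FeatureTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> FeatureTable:
    """Centered log-ratio per sample: ln(v + pc) minus its mean over features."""
    _require_kind(table, "relative_abundance")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logs = np.log(table.values + pseudocount)
    centered = logs - logs.mean(axis=0, keepdims=True)
    return FeatureTable(
        list(table.feature_ids), list(table.sample_ids), centered, "clr"
    )


def transform_counts(
    table: FeatureTable, method: str, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> FeatureTable:
    """Apply one of the four named representations to a raw count table."""
    _require_kind(table, "count")
    if method == "binarize":
        return binarize(table)
    rel = to_relative_abundance(table)
    if method in ("relabund", "relative_abundance"):
        return rel
    if method == "log2":
        return log2_transform(rel, pseudocount)
    if method == "clr":
        return clr_transform(rel, pseudocount)
    raise ValueError(
        f"unknown transform {method!r}; expected binarize, relabund, log2 or clr"
    )


class MicrobiomePreprocessor(TransformerMixin, BaseEstimator):
    """scikit-learn transformer form of the count-table representations.

    Operates on (n_samples, n_features) count arrays, the estimator-side
    orientation, so it composes with pipelines. ``method`` is one of
    ``binarize``, ``relative_abundance``, ``log2``, ``clr``; the latter three
    normalize each sample to proportions first.

    Stateless (``fit`` only records the feature count).
    """

    def __init__(self, method: str = "binarize", pseudocount: float = DEFAULT_PSEUDOCOUNT):
        self.method = method
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        if self.method not in ("binarize", "relative_abundance", "relabund", "log2", "clr"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method in ("log2", "clr") and self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        table = FeatureTable(
            [f"f{i}" for i in range(X.shape[1])],
            [f"s{j}" for j in range(X.shape[0])],
            X.T,
            "count",
        )
        method = "relabund" if self.method == "relative_abundance" else self.method
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return transform_counts(table, method, self.pseudocount).values.T
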