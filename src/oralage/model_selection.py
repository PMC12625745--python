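"""Evaluation protocol: hold-out split, bin-width tuning, MAE reporting,
regression baselines, sex covariate handling, and paired error comparison.

The hold-out split mirrors the cohort protocol: three validation samples are
drawn from each of five age strata (20-29, 30-39, 40-49, 50-59, >= 60),
restricted to ages represented by at least two individuals, giving a fixed
15-sample validation set; everything else trains. Bin width is tuned by
k-fold cross-validated MAE on the training set over a width grid, ties
breaking toward the smaller width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .ensemble import BinnedVotingAgeRegressor, _as_range
from .feature_selection import LassoStabilitySelector
from .io import FeatureTable, SampleMetadata, ValidationError, ages_vector
from .learners import DEFAULT_SEED, LearnerSpec, make_regressor

logger = logging.getLogger(__name__)

VALIDATION_STRATA: tuple[tuple[int, Optional[int]], ...] = (
    (20, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, None),
)
SAMPLES_PER_STRATUM = 3


@dataclass
class EvaluationReport:
    """Per-sample predictions with overall and subgroup MAE (years)."""

    per_sample: pd.DataFrame  # sample_id, true_age, predicted_age, absolute_error
    mae: float
    subgroup_mae: dict[str, float]
    n: int


def stratified_validation_split(
    meta: Sequence[SampleMetadata], seed: int = DEFAULT_SEED
) -> tuple[list[str], list[str]]:
    """Draw the 3-per-stratum validation set; return (train_ids, val_ids).

    Only ages shared by at least two individuals are eligible for the draw,
    so no age disappears entirely from training.
    """
    rng = np.random.default_rng(seed)
    ages = ages_vector(meta)
    age_counts = pd.Series(ages).value_counts()
    eligible_ages = set(age_counts[age_counts >= 2].index)
    validation: list[str] = []
    for lo, hi in VALIDATION_STRATA:
        pool = [
            m.sample_id
            for m in meta
            if m.age >= lo and (hi is None or m.age <= hi) and m.age in eligible_ages
        ]
        label = f"{lo}-{hi if hi is not None else ''}"
        if len(pool) < SAMPLES_PER_STRATUM:
            raise ValidationError(
                f"stratum {label}: only {len(pool)} eligible samples, "
                f"need {SAMPLES_PER_STRATUM}"
            )
        validation.extend(rng.choice(pool, size=SAMPLES_PER_STRATUM, replace=False))
    val_set = set(validation)
    train = [m.sample_id for m in meta if m.sample_id not in val_set]
    return train, validation


def evaluate(
    model,
    table: FeatureTable,
    meta_or_ages,
    subgroup: Optional[tuple[int, int]] = (20, 59),
) -> EvaluationReport:
    """Predict every sample in ``table`` and report MAE overall and within
    the inclusive ``subgroup`` age interval (default 20-59; None skips the
    subgroup breakdown)."""
    if table.n_samples == 0:
        raise ValidationError("empty evaluation set")
    if len(meta_or_ages) and isinstance(meta_or_ages[0], SampleMetadata):
        ages = ages_vector(meta_or_ages)
    else:
        ages = np.asarray(meta_or_ages)
    preds = np.asarray(model.predict(table.samples_array()), dtype=float)
    errors = np.abs(ages - preds)
    per_sample = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "true_age": ages,
            "predicted_age": preds,
            "absolute_error": errors,
        }
    )
    subgroup_mae = {}
    if subgroup is not None:
        lo, hi = subgroup
        in_sub = (ages >= lo) & (ages <= hi)
        if not in_sub.any():
            raise ValidationError(f"no samples in subgroup {lo}-{hi}")
        subgroup_mae[f"{lo}-{hi}"] = float(errors[in_sub].mean())
    return EvaluationReport(
        per_sample=per_sample,
        mae=float(errors.mean()),
        subgroup_mae=subgroup_mae,
        n=len(ages),
    )


def grid_search_bin_width(
    X,
    ages,
    widths: Sequence[int] = tuple(range(1, 65)),
    folds: int = 10,
    base_learner: LearnerSpec = "xgboost",
    age_range=(1, 80),
    seed: int = DEFAULT_SEED,
) -> tuple[int, pd.DataFrame]:
    """Choose the bin width minimizing k-fold CV MAE on the training set.

    Widths whose schemes end up with a single occupied bin in some fold are
    marked infeasible (MAE = NaN) and logged, not fatal. Ties break toward
    the smaller width.
    """
    X = np.asarray(X, dtype=float)
    ages = np.asarray(ages, dtype=int)
    rng = _as_range(age_range)
    span = rng.hi - rng.lo + 1
    for w in widths:
        if not 1 <= w <= span:
            raise ValueError(f"width {w} outside [1, {span}]")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    rows = []
    for w in widths:
        fold_maes = []
        feasible = True
        for tr, te in splits:
            model = BinnedVotingAgeRegressor(
                bin_width=w,
                age_range=age_range,
                base_learner=base_learner,
                random_state=seed,
            )
            try:
                model.fit(X[tr], ages[tr])
            except ValueError as exc:
                logger.warning("bin width %d infeasible: %s", w, exc)
                feasible = False
                break
            fold_maes.append(float(np.abs(model.predict(X[te]) - ages[te]).mean()))
        rows.append(
            {
                "bin_width": w,
                "cv_mae": float(np.mean(fold_maes)) if feasible else np.nan,
                "feasible": feasible,
            }
        )
    table = pd.DataFrame(rows)
    feasible = table.dropna(subset=["cv_mae"])
    if feasible.empty:
        raise ValidationError("no feasible bin width in the grid")
    # idxmin returns the first minimum; widths are scanned in given order,
    # so pass an ascending grid for smallest-width tie-breaking
    best = int(feasible.loc[feasible["cv_mae"].idxmin(), "bin_width"])
    return best, table


def fit_traditional_regressor(
    X, ages, base_learner: LearnerSpec = "xgboost", random_state: int = DEFAULT_SEED
):
    """Fit a direct regression baseline (KNN/MLP/RF/SVR/XGBoost).

    Predictions stay real-valued; MAE on them is reported unrounded.
    """
    reg = make_regressor(base_learner, random_state)
    return reg.fit(np.asarray(X, dtype=float), np.asarray(ages, dtype=float))


def add_sex_dummy(table: FeatureTable, meta: Sequence[SampleMetadata]) -> FeatureTable:
    """Append a ``sex_dummy`` feature row (female = 0, male = 1).

    Samples with missing sex are an error — they must be excluded upstream.
    """
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in table.sample_ids if s not in by_id or by_id[s].sex is None]
    if missing:
        raise ValidationError(f"samples with missing sex information: {missing}")
    if "sex_dummy" in table.feature_ids:
        raise ValidationError("table already has a sex_dummy feature")
    row = np.array(
        [[1.0 if by_id[s].sex == "male" else 0.0 for s in table.sample_ids]]
    )
    return FeatureTable(
        table.feature_ids + ["sex_dummy"],
        list(table.sample_ids),
        np.vstack([table.values, row]),
        table.value_kind,
    )


def compare_absolute_errors(
    report_a: EvaluationReport, report_b: EvaluationReport
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-sample absolute
    errors. Identical error vectors return (0, 1) by convention."""
    a = report_a.per_sample.set_index("sample_id")["absolute_error"]
    b = report_b.per_sample.set_index("sample_id")["absolute_error"]
    if set(a.index) != set(b.index):
        raise ValidationError("reports cover different sample sets")
    b = b.reindex(a.index)
    diffs = a.to_numpy() - b.to_numpy()
    if np.allclose(diffs, 0):
        return 0.0, 1.0
    res = stats.wilcoxon(a.to_numpy(), b.to_numpy())
    return float(res.statistic), float(res.pvalue)


@dataclass
class CVResult:
    fold_reports: list[EvaluationReport]
    mean_mae: float
    sd_mae: float
    fold_selected: list[list[str]]  # features chosen inside each fold


def kfold_cv_pipeline(
    table: FeatureTable,
    meta: Sequence[SampleMetadata],
    folds: int = 5,
    seed: int = DEFAULT_SEED,
    bin_width: int = 32,
    age_range=(1, 80),
    base_learner: LearnerSpec = "xgboost",
    selection_params: Optional[dict] = None,
) -> CVResult:
    """k-fold CV with per-fold feature selection (no test-fold leakage).

    In each fold, stability selection runs on the training portion only; the
    ensemble is fitted on the selected features and scored on the held-out
    fold. Reports per-fold MAEs and their mean +/- sd.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    sel_params = dict(selection_params or {})
    ages = ages_vector(meta)
    X = table.samples_array()
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    fold_selected: list[list[str]] = []
    for fold_i, (tr, te) in enumerate(kf.split(X)):
        selector = LassoStabilitySelector(**sel_params)
        selector.fit(X[tr], ages[tr])
        if not selector.support_.any():
            raise ValidationError(f"fold {fold_i}: stability selection kept no features")
        selected = [f for f, keep in zip(table.feature_ids, selector.support_) if keep]
        fold_selected.append(selected)
        model = BinnedVotingAgeRegressor(
            bin_width=bin_width,
            age_range=age_range,
            base_learner=base_learner,
            random_state=seed,
        ).fit(selector.transform(X[tr]), ages[tr])
        fold_table = table.select_samples(
            [table.sample_ids[i] for i in te]
        ).select_features(selected)
        reports.append(evaluate(model, fold_table, ages[te], subgroup=None))
    maes = np.array([r.mae for r in reports])
    return CVResult(reports, float(maes.mean()), float(maes.std(ddof=1)), fold_selected)
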