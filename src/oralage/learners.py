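"""Registry of base learners.

Eight classification algorithms are available as ensemble members (KNN, LDA,
logistic regression, Gaussian naive Bayes, a multilayer perceptron, random
forest, SVM, XGBoost) and five as traditional direct-regression baselines
(KNN, MLP, random forest, SVR, XGBoost). A spec is either a name or
``(name, params)``; params override the defaults below, which are kept small
— exhaustive per-algorithm grids belong in configuration, not defaults.
XGBoost is the default member algorithm.
"""

from __future__ import annotations

from typing import Any, Mapping, Optional, Union

from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR
from xgboost import XGBClassifier, XGBRegressor

LearnerSpec = Union[str, tuple[str, Mapping[str, Any]]]

#: Default seed for every stochastic procedure in the package.
DEFAULT_SEED = 8

_XGB_DEFAULTS = dict(
    n_estimators=100,
    max_depth=3,
    learning_rate=0.1,
    subsample=1.0,
    colsample_bytree=1.0,
    n_jobs=1,
    verbosity=0,
)

_CLASSIFIERS: dict[str, tuple[type, dict, bool]] = {
    # name -> (class, default params, accepts random_state)
    "knn": (KNeighborsClassifier, dict(n_neighbors=5), False),
    "lda": (LinearDiscriminantAnalysis, dict(), False),
    "logistic": (LogisticRegression, dict(max_iter=10000), True),
    "naive_bayes": (GaussianNB, dict(), False),
    "neural_network": (MLPClassifier, dict(hidden_layer_sizes=(50,), max_iter=1000), True),
    "random_forest": (RandomForestClassifier, dict(n_estimators=100), True),
    "svm": (SVC, dict(), True),
    "xgboost": (XGBClassifier, dict(_XGB_DEFAULTS), True),
}

_REGRESSORS: dict[str, tuple[type, dict, bool]] = {
    "knn": (KNeighborsRegressor, dict(n_neighbors=5), False),
    "neural_network": (MLPRegressor, dict(hidden_layer_sizes=(50,), max_iter=1000), True),
    "random_forest": (RandomForestRegressor, dict(n_estimators=100), True),
    "svr": (SVR, dict(), False),
    "xgboost": (XGBRegressor, dict(_XGB_DEFAULTS), True),
}

CLASSIFIER_NAMES = tuple(_CLASSIFIERS)
REGRESSOR_NAMES = tuple(_REGRESSORS)


def _parse_spec(spec: LearnerSpec) -> tuple[str, dict]:
    if isinstance(spec, str):
        return spec, {}
    name, params = spec
    return name, dict(params)


def _build(registry: Mapping[str, tuple[type, dict, bool]], kind: str,
           spec: LearnerSpec, random_state: Optional[int]):
    name, overrides = _parse_spec(spec)
    if name not in registry:
        raise ValueError(
            f"unknown {kind} learner {name!r}; available: {sorted(registry)}"
        )
    cls, defaults, seeded = registry[name]
    params = {**defaults, **overrides}
    if seeded and "random_state" not in params and random_state is not None:
        params["random_state"] = random_state
    return cls(**params)


def make_classifier(spec: LearnerSpec, random_state: Optional[int] = DEFAULT_SEED):
    """Instantiate an (unfitted) classifier from a learner spec."""
    return _build(_CLASSIFIERS, "classification", spec, random_state)


def make_regressor(spec: LearnerSpec, random_state: Optional[int] = DEFAULT_SEED):
    """Instantiate an (unfitted) regressor from a learner spec."""
    return _build(_REGRESSORS, "regression", spec, random_state)
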