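"""Learner specifications: the four regression learners compared in the
pipeline (lasso as the linear baseline; random forest, LightGBM and XGBoost
as tree ensembles), their fixed parameters, and their random hyperparameter
search spaces.

The random forest defaults are the fixed configuration used for the main
feature-group models (100 trees, depth 5, min 5 samples per leaf, min 2 to
split, 10 features per split capped at the matrix width); its search is
therefore disabled by default. Note regression trees split on squared
error — a "Gini" criterion only exists for classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

# lightgbm's sklearn wrapper invents feature names for plain arrays and then
# warns on every predict; the arrays are consistent, the warning is noise
warnings.filterwarnings("ignore", message="X does not have valid feature names")
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso

__all__ = ["LearnerSpec", "LEARNER_KINDS", "build_estimator", "sample_search_params"]

LEARNER_KINDS = ("lasso", "random_forest", "gradient_boosting_lgb", "gradient_boosting_xgb")

_FIXED_DEFAULTS: dict[str, dict[str, Any]] = {
    "lasso": {"alpha": 0.1, "max_iter": 10_000},
    "random_forest": {
        "n_estimators": 100,
        "criterion": "squared_error",
        "max_depth": 5,
        "min_samples_leaf": 5,
        "min_samples_split": 2,
        "max_features": 10,
    },
    "gradient_boosting_lgb": {
        "n_estimators": 100,
        "learning_rate": 0.1,
        "num_leaves": 31,
        "min_child_samples": 10,
    },
    "gradient_boosting_xgb": {
        "n_estimators": 100,
        "learning_rate": 0.1,
        "max_depth": 4,
        "min_child_weight": 5,
    },
}

# sampler spec: ("log", lo, hi) continuous log-uniform; ("int", lo, hi) uniform integer
_SEARCH_DEFAULTS: dict[str, dict[str, tuple]] = {
    # lower bound 1e-3: below that the penalty is inactive at n~110 and
    # coordinate descent converges very slowly for no accuracy gain
    "lasso": {"alpha": ("log", 1e-3, 10.0)},
    "random_forest": {
        "max_depth": ("int", 3, 10),
        "min_samples_leaf": ("int", 2, 10),
        "max_features": ("int", 3, 20),
    },
    "gradient_boosting_lgb": {
        "learning_rate": ("log", 0.01, 0.3),
        "num_leaves": ("int", 7, 63),
        "min_child_samples": ("int", 5, 30),
    },
    "gradient_boosting_xgb": {
        "learning_rate": ("log", 0.01, 0.3),
        "max_depth": ("int", 2, 6),
        "min_child_weight": ("int", 1, 10),
    },
}


@dataclass
class LearnerSpec:
    """One learner: kind, fixed parameters, and optional random search.

    ``search_iterations`` random draws from ``search_space`` are scored by
    inner cross-validation inside each training fold; 0 disables the search
    and uses the fixed parameters as-is (the random-forest default, whose
    parameters are fixed by convention).
    """

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    search_iterations: int = 10
    search_space: dict[str, tuple] | None = None

    def __post_init__(self) -> None:
        if self.kind not in LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}; expected {LEARNER_KINDS}")
        if self.search_space is None:
            self.search_space = dict(_SEARCH_DEFAULTS[self.kind])

    @classmethod
    def default(cls, kind: str) -> "LearnerSpec":
        """The out-of-the-box spec for a learner kind: search on for all
        learners except the fixed-parameter random forest."""
        return cls(kind=kind, search_iterations=0 if kind == "random_forest" else 10)

    @property
    def is_tree_ensemble(self) -> bool:
        return self.kind != "lasso"

    def resolved_params(self, overrides: dict[str, Any] | None = None) -> dict[str, Any]:
        p = dict(_FIXED_DEFAULTS[self.kind])
        p.update(self.params)
        if overrides:
            p.update(overrides)
        return p


def sample_search_params(spec: LearnerSpec, rng: np.random.Generator) -> dict[str, Any]:
    """Draw one random configuration from the spec's search space."""
    out: dict[str, Any] = {}
    for name, (kind, lo, hi) in spec.search_space.items():
        if kind == "log":
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "int":
            out[name] = int(rng.integers(lo, hi + 1))
        else:
            raise ValueError(f"unknown sampler {kind!r} for {name}")
    return out


def build_estimator(
    spec: LearnerSpec,
    n_features: int,
    random_state: int,
    overrides: dict[str, Any] | None = None,
) -> BaseEstimator:
    """Instantiate the sklearn-API estimator for a spec.

    ``max_features`` is capped at the matrix width (a 10-feature cap is
    meaningless for the 6-column physiochemical group). All estimators are
    single-threaded for reproducibility.
    """
    p = spec.resolved_params(overrides)
    if spec.kind == "lasso":
        return Lasso(random_state=random_state, **p)
    if spec.kind == "random_forest":
        p["max_features"] = min(p["max_features"], n_features)
        if str(p.get("criterion", "")).lower() == "gini":
            p["criterion"] = "squared_error"  # Gini is classification-only
        return RandomForestRegressor(random_state=random_state, n_jobs=1, **p)
    if spec.kind == "gradient_boosting_lgb":
        import lightgbm as lgb

        return lgb.LGBMRegressor(
            random_state=random_state, n_jobs=1, verbose=-1, deterministic=True, **p
        )
    if spec.kind == "gradient_boosting_xgb":
        import xgboost as xgb

        return xgb.XGBRegressor(random_state=random_state, n_jobs=1, verbosity=0, **p)
    raise AssertionError(spec.kind)
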