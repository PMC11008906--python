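"""Gradient-boosted tree age-group classifier over the named feature sets.

The estimator wraps XGBoost with the hyperparameters found optimal for
this task (max_depth=10, max_leaves=10, learning_rate=0.008), restricts
the feature matrix to one of the named subsets (HRV, SR, or HRV+SR),
imputes missing features by the training-set median, and optionally
rebalances the training set by random oversampling of minority classes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin

from ..features import HRV_FEATURES, SR_FEATURES
from ..preprocess import random_oversample

FEATURE_SUBSETS = ("HRV", "SR", "HRV+SR")


def subset_columns(feature_subset: str) -> list:
    if feature_subset == "HRV":
        return list(HRV_FEATURES)
    if feature_subset == "SR":
        return list(SR_FEATURES)
    if feature_subset == "HRV+SR":
        return list(HRV_FEATURES) + list(SR_FEATURES)
    raise ValueError(f"unknown feature subset {feature_subset!r}")


class FeatureAgeClassifier(BaseEstimator, ClassifierMixin):
    """XGBoost age-group classifier on record-level HRV/SR feature rows."""

    def __init__(
        self,
        feature_subset: str = "HRV+SR",
        balanced: bool = True,
        max_depth: int = 10,
        max_leaves: int = 10,
        learning_rate: float = 0.008,
        n_estimators: int = 300,
        min_child_weight: float = 1e-3,
        seed: int = 0,
    ):
        self.feature_subset = feature_subset
        self.balanced = balanced
        self.max_depth = max_depth
        self.max_leaves = max_leaves
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        # softprob hessians are ~p(1-p) per row; the library default of 1
        # blocks all splits on cohorts of tens of records per class
        self.min_child_weight = min_child_weight
        self.seed = seed

    def _transform(self, X: pd.DataFrame, fit: bool = False) -> pd.DataFrame:
        cols = subset_columns(self.feature_subset)
        missing_cols = [c for c in cols if c not in X.columns]
        if missing_cols:
            raise ValueError(f"feature matrix lacks columns {missing_cols}")
        X = X[cols].astype(float)
        if fit:
            all_nan = [c for c in cols if X[c].isna().all()]
            if all_nan:
                warnings.warn(f"dropping all-missing feature columns {all_nan}")
            self.feature_names_ = [c for c in cols if c not in all_nan]
            self.medians_ = X[self.feature_names_].median()
        X = X[self.feature_names_].fillna(self.medians_)
        return X

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y)
        Xt = self._transform(X, fit=True)
        self.classes_ = np.unique(y)
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_to_idx[c] for c in y])
        rows = list(range(len(Xt)))
        if self.balanced:
            rows, yi = random_oversample(rows, list(yi), seed=self.seed)
            yi = np.asarray(yi)
        Xfit = Xt.iloc[rows]
        self.booster_model_ = xgb.XGBClassifier(
            objective="multi:softprob",
            num_class=len(self.classes_),
            max_depth=self.max_depth,
            max_leaves=self.max_leaves,
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            min_child_weight=self.min_child_weight,
            tree_method="hist",
            n_jobs=1,
            random_state=self.seed,
            verbosity=0,
        )
        self.booster_model_.fit(Xfit, yi)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Xt = self._transform(X)
        return self.booster_model_.predict_proba(Xt)

    def predict(self, X: pd.DataFrame):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def margins(self, X: pd.DataFrame) -> np.ndarray:
        """Pre-softmax margin output per class (the scale SHAP values sum on)."""
        Xt = self._transform(X)
        booster = self.booster_model_.get_booster()
        dm = xgb.DMatrix(Xt)
        return booster.predict(dm, output_margin=True)
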