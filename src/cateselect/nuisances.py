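"""Nuisance estimation: propensity e(x) and conditional mean outcome m(x).

Both nuisances are fitted with a two-member stack — a penalized linear model
and histogram gradient-boosted trees — whose hyperparameters are chosen by an
inner cross-validated grid search on the training set before the tuned
members are combined through a linear meta-learner trained on out-of-fold
predictions.  The propensity stack is scored by the Brier score (minimized by
the true conditional probability); the outcome stack by mean squared error.
``m`` regresses y on x only, ignoring the treatment: it targets
E[Y | X = x] over the factual distribution, the quantity entering the
residual-on-residual (R) decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold, cross_val_predict

__all__ = [
    "NuisanceConfig",
    "NuisanceEstimates",
    "fit_nuisances",
    "brier_score",
    "bound_propensity",
]

# Hyperparameter grids for the inner search.  Deliberately small: the stack's
# flexibility comes from combining a linear and a tree member, not from a
# wide grid.  Boosting members use 60 trees of <= 31 leaves — ample for the
# sample sizes and smooth targets the stack is asked to fit.
_LOGISTIC_GRID = {"C": [0.01, 0.1, 1.0, 10.0]}
_RIDGE_GRID = {"alpha": [0.01, 1.0, 100.0]}
_GBT_GRID = {"learning_rate": [0.1, 0.5]}


@dataclass(frozen=True)
class NuisanceConfig:
    """Fold counts, propensity floor and the optional separate nuisance set.

    ``outer_folds`` build the out-of-fold predictions the stack combiner is
    trained on; ``inner_folds`` drive the hyperparameter grid search.
    ``eta`` is the floor used when risks divide by e or 1-e (applied there,
    not here).  With ``separate_set`` the selection procedure carves a
    dedicated fraction of the training rows for nuisance fitting.
    """

    outer_folds: int = 5
    inner_folds: int = 3
    eta: float = 1e-3
    separate_set: bool = False
    separate_fraction: float = 0.5
    random_state: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.eta < 0.5):
            raise ValueError("eta must lie in (0, 0.5)")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not (0 < self.separate_fraction < 1):
            raise ValueError("separate_fraction must lie in (0, 1)")


class _Stack:
    """Linear combiner over tuned members, trained on out-of-fold predictions."""

    def __init__(self, members, meta, predict_fn):
        self.members = members
        self.meta = meta
        self._predict_fn = predict_fn

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([self._predict_fn(m, X) for m in self.members])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.meta.predict(self.member_predictions(X))

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        return self.meta.predict_proba(self.member_predictions(X))[:, 1]


@dataclass
class NuisanceEstimates:
    """Fitted plug-in nuisances with provenance.

    ``e_hat(X)`` returns probabilities strictly inside (0, 1); ``m_hat(X)``
    returns the estimated conditional mean outcome.  ``fit_report`` records
    the chosen hyperparameters and cross-validated scores (Brier for the
    propensity, MSE for the outcome).  ``source`` says whether the fit used
    the shared training set or a dedicated nuisance split.
    """

    _e_stack: Any = field(repr=False)
    _m_stack: Any = field(repr=False)
    fit_report: dict = field(default_factory=dict)
    source: str = "shared-train"

    def e_hat(self, X: np.ndarray) -> np.ndarray:
        p = self._e_stack.predict_proba1(np.atleast_2d(np.asarray(X, dtype=float)))
        # the logistic combiner cannot hit 0/1 except by overflow; keep strict
        return np.clip(p, 1e-12, 1 - 1e-12)

    def m_hat(self, X: np.ndarray) -> np.ndarray:
        return self._m_stack.predict(np.atleast_2d(np.asarray(X, dtype=float)))


def brier_score(p: np.ndarray, a: np.ndarray) -> float:
    """Mean squared distance between predicted probabilities and outcomes."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    if p.shape != a.shape:
        raise ValueError("probability and outcome vectors must have equal length")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - a) ** 2))


def bound_propensity(e: np.ndarray, eta: float = 1e-3) -> np.ndarray:
    """Clip propensities into [eta, 1 - eta]; identity on interior vectors."""
    if not (0 < eta < 0.5):
        raise ValueError(f"eta must lie in (0, 0.5), got {eta}")
    e = np.asarray(e, dtype=float)
    if (e < 0).any() or (e > 1).any():
        raise ValueError("propensities must lie in [0, 1]")
    return np.clip(e, eta, 1.0 - eta)


def _tune(estimator, grid, X, y, cv, scoring):
    gs = GridSearchCV(estimator, grid, cv=cv, scoring=scoring, refit=False)
    gs.fit(X, y)
    return gs.best_params_, float(gs.best_score_)


def fit_nuisances(
    train, config: NuisanceConfig | None = None
) -> NuisanceEstimates:
    """Fit the propensity and mean-outcome stacks on a training set.

    Hyperparameters of each member are selected by an inner grid search
    (``inner_folds``, Brier score for the classifier members, MSE for the
    regressors); the tuned members are then cross-fitted over
    ``outer_folds`` to produce out-of-fold predictions on which the linear
    combiner is trained, and finally refitted on the full training set.
    """
    config = config or NuisanceConfig()
    X, a, y = train.X, np.asarray(train.a), np.asarray(train.y, dtype=float)
    if len(np.unique(a)) < 2:
        raise ValueError("training data contain a single treatment arm")
    if not np.isfinite(y).all():
        raise ValueError("outcome contains non-finite values")
    rs = config.random_state
    report: dict = {}

    # --- propensity stack -------------------------------------------------
    inner = StratifiedKFold(config.inner_folds, shuffle=True, random_state=rs)
    outer = StratifiedKFold(config.outer_folds, shuffle=True, random_state=rs + 1)
    lr_params, lr_brier = _tune(
        LogisticRegression(max_iter=1000), _LOGISTIC_GRID, X, a, inner,
        "neg_brier_score",
    )
    gbt_params, gbt_brier = _tune(
        HistGradientBoostingClassifier(
            early_stopping=False, max_iter=60, random_state=rs
        ),
        _GBT_GRID, X, a, inner, "neg_brier_score",
    )
    members_e = [
        LogisticRegression(max_iter=1000, **lr_params),
        HistGradientBoostingClassifier(
            early_stopping=False, max_iter=60, random_state=rs, **gbt_params
        ),
    ]
    oof_e = np.column_stack(
        [
            cross_val_predict(m, X, a, cv=outer, method="predict_proba")[:, 1]
            for m in members_e
        ]
    )
    meta_e = LogisticRegression(max_iter=1000).fit(oof_e, a)
    for m in members_e:
        m.fit(X, a)
    e_stack = _Stack(members_e, meta_e, lambda m, Z: m.predict_proba(Z)[:, 1])
    oof_brier = brier_score(meta_e.predict_proba(oof_e)[:, 1], a)
    report["e"] = {
        "linear": {"params": lr_params, "cv_brier": -lr_brier},
        "boosting": {"params": gbt_params, "cv_brier": -gbt_brier},
        "stack_oof_brier": oof_brier,
    }

    # --- conditional mean outcome stack (y ~ x, treatment ignored) --------
    inner_r = KFold(config.inner_folds, shuffle=True, random_state=rs)
    outer_r = KFold(config.outer_folds, shuffle=True, random_state=rs + 1)
    ridge_params, ridge_mse = _tune(
        Ridge(), _RIDGE_GRID, X, y, inner_r, "neg_mean_squared_error"
    )
    gbtr_params, gbtr_mse = _tune(
        HistGradientBoostingRegressor(
            early_stopping=False, max_iter=60, random_state=rs
        ),
        _GBT_GRID, X, y, inner_r, "neg_mean_squared_error",
    )
    members_m = [
        Ridge(**ridge_params),
        HistGradientBoostingRegressor(
            early_stopping=False, max_iter=60, random_state=rs, **gbtr_params
        ),
    ]
    oof_m = np.column_stack(
        [cross_val_predict(m, X, y, cv=outer_r) for m in members_m]
    )
    # nonnegative weights: a convex-ish combination of members
    meta_m = LinearRegression(positive=True).fit(oof_m, y)
    for m in members_m:
        m.fit(X, y)
    m_stack = _Stack(members_m, meta_m, lambda m, Z: m.predict(Z))
    oof_mse = float(np.mean((meta_m.predict(oof_m) - y) ** 2))
    report["m"] = {
        "linear": {"params": ridge_params, "cv_mse": -ridge_mse},
        "boosting": {"params": gbtr_params, "cv_mse": -gbtr_mse},
        "stack_oof_mse": oof_mse,
    }

    return NuisanceEstimates(
        _e_stack=e_stack, _m_stack=m_stack, fit_report=report,
        source="shared-train",
    )
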