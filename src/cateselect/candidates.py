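"""Candidate outcome-model families and the CATE they induce.

An outcome model f(x, a) predicts the outcome under either arm; contrasting
its two arms gives a plug-in CATE estimate tau_f(x) = f(x, 1) - f(x, 0) and,
averaged, an ATE estimate.  Three meta-learner strategies are supported:

- SLearner: a single regressor on (x, a), treatment appended as a feature;
- SftLearner: one shared random featurization, two per-arm regressors;
- TLearner: fully separate featurizations and regressors per arm.

Two concrete families are built in: a 120-member grid of ridge regressions on
random two-knot Gaussian-kernel features (6 penalties x {T, Sft} x 10 random
featurizations), and an 18-member SLearner grid of histogram gradient-boosted
trees (3 learning rates x 6 leaf-node caps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.ensemble import (
    HistGradientBoostingRegressor,
)
from sklearn.linear_model import Ridge
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .simulator import CausalDataset, rbf_features

__all__ = [
    "CandidateSpec",
    "FittedCandidate",
    "build_caussim_family",
    "build_gbt_family",
    "fit_candidate",
    "fit_family",
    "predict_cate",
    "estimate_ate",
    "RIDGE_PENALTIES",
    "GBT_LEARNING_RATES",
    "GBT_MAX_LEAF_NODES",
]

RIDGE_PENALTIES = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2)
GBT_LEARNING_RATES = (0.01, 0.1, 1.0)
GBT_MAX_LEAF_NODES = (25, 27, 30, 32, 35, 40)

#: number of random knots in a candidate featurization
N_CANDIDATE_KNOTS = 2


@dataclass(frozen=True)
class CandidateSpec:
    """Description of one candidate outcome model.

    ``base_model`` is ``"ridge-on-rbf"`` (uses ``regularization`` and
    ``featurization_seed``) or ``"gradient-boosting"`` (uses
    ``learning_rate`` and ``max_leaf_nodes``).  ``knots``/``bandwidth``
    optionally pin the featurization instead of drawing it at random — useful
    to construct a well-specified candidate on simulated data.
    """

    learner_kind: str  # SLearner | SftLearner | TLearner
    base_model: str = "ridge-on-rbf"
    featurization_seed: int = 0
    regularization: float | None = None
    learning_rate: float | None = None
    max_leaf_nodes: int | None = None
    identifier: str = ""
    knots: tuple | None = field(default=None, compare=False)
    bandwidth: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.learner_kind not in ("SLearner", "SftLearner", "TLearner"):
            raise ValueError(f"unknown learner_kind {self.learner_kind!r}")
        if self.base_model not in ("ridge-on-rbf", "gradient-boosting"):
            raise ValueError(f"unknown base_model {self.base_model!r}")
        if self.base_model == "ridge-on-rbf":
            if self.regularization is None or self.regularization <= 0:
                raise ValueError("ridge candidates need a positive regularization")
        else:
            if self.learning_rate is None or self.max_leaf_nodes is None:
                raise ValueError("boosting candidates need learning_rate and max_leaf_nodes")


def build_caussim_family(n_bases: int = 10, seed: int = 0) -> list[CandidateSpec]:
    """Ridge-on-random-kernel family: 6 penalties x {TLearner, SftLearner}
    x ``n_bases`` featurization seeds (120 members with the defaults)."""
    if n_bases < 1:
        raise ValueError("n_bases must be >= 1")
    feat_seeds = np.random.SeedSequence(seed).generate_state(n_bases) % (2**31)
    specs = []
    for b, fs in enumerate(feat_seeds):
        for kind in ("TLearner", "SftLearner"):
            for lam in RIDGE_PENALTIES:
                specs.append(
                    CandidateSpec(
                        learner_kind=kind,
                        base_model="ridge-on-rbf",
                        featurization_seed=int(fs),
                        regularization=lam,
                        identifier=f"ridge_{kind.lower()}_basis{b:02d}_lam{lam:g}",
                    )
                )
    return specs


def build_gbt_family() -> list[CandidateSpec]:
    """Gradient-boosting SLearner grid: 3 learning rates x 6 leaf-node caps."""
    return [
        CandidateSpec(
            learner_kind="SLearner",
            base_model="gradient-boosting",
            learning_rate=lr,
            max_leaf_nodes=mln,
            identifier=f"gbt_slearner_lr{lr:g}_leaves{mln}",
        )
        for lr in GBT_LEARNING_RATES
        for mln in GBT_MAX_LEAF_NODES
    ]


def _median_heuristic_bandwidth(X: np.ndarray, rng: np.random.Generator) -> float:
    """Median pairwise distance on a subsample; standard kernel-width default."""
    n = len(X)
    idx = rng.choice(n, size=min(n, 200), replace=False)
    d = pdist(X[idx])
    med = float(np.median(d)) if len(d) else 1.0
    return med if med > 0 else 1.0


def _draw_featurization(
    X: np.ndarray, rng: np.random.Generator, bandwidth: float | None
) -> tuple[np.ndarray, float]:
    """Two knots drawn from the training rows + median-heuristic bandwidth."""
    idx = rng.choice(len(X), size=min(len(X), N_CANDIDATE_KNOTS), replace=False)
    h = bandwidth if bandwidth is not None else _median_heuristic_bandwidth(X, rng)
    return X[idx].copy(), h


def _ridge_pipeline(lam: float):
    # intercept fitted unpenalized; features standardized before the penalty
    return make_pipeline(StandardScaler(), Ridge(alpha=lam, fit_intercept=True))


class FittedCandidate:
    """A fitted outcome model exposing per-arm predictions and the induced CATE.

    Not constructed directly; use :func:`fit_candidate`.
    """

    def __init__(self, spec: CandidateSpec, arms, train_indices=None):
        self.spec = spec
        self._arms = arms  # dict with structure depending on learner kind
        self.train_indices = (
            None if train_indices is None else np.asarray(train_indices)
        )

    @property
    def identifier(self) -> str:
        return self.spec.identifier

    def _predict_arm(self, X: np.ndarray, arm: int) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        kind = self.spec.learner_kind
        if kind == "SLearner":
            model = self._arms["model"]
            if self.spec.base_model == "ridge-on-rbf":
                knots, h = self._arms["featurization"]
                feats = rbf_features(X, knots, h)
            else:
                feats = X
            fa = np.column_stack([feats, np.full(len(X), float(arm))])
            return model.predict(fa)
        if kind == "SftLearner":
            knots, h = self._arms["featurization"]
            feats = rbf_features(X, knots, h)
            return self._arms[f"model{arm}"].predict(feats)
        # TLearner
        knots, h = self._arms[f"featurization{arm}"]
        feats = rbf_features(X, knots, h)
        return self._arms[f"model{arm}"].predict(feats)

    def mu0_hat(self, X: np.ndarray) -> np.ndarray:
        return self._predict_arm(X, 0)

    def mu1_hat(self, X: np.ndarray) -> np.ndarray:
        return self._predict_arm(X, 1)

    def predict(self, X: np.ndarray, a: np.ndarray) -> np.ndarray:
        """Factual prediction f(x_i; a_i)."""
        a = np.asarray(a)
        out = np.empty(len(a), dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        for arm in (0, 1):
            mask = a == arm
            if mask.any():
                out[mask] = self._predict_arm(X[mask], arm)
        return out

    def predict_cate(self, X: np.ndarray) -> np.ndarray:
        return self.mu1_hat(X) - self.mu0_hat(X)


def _draw_spec_featurizations(spec: CandidateSpec, X, a) -> dict:
    """Featurizations a ridge spec needs, keyed by arm (None = shared).

    Deterministic in ``featurization_seed``, so specs differing only in the
    penalty share them; :func:`fit_family` exploits this through a cache.
    """
    rng = np.random.default_rng(spec.featurization_seed)
    if spec.learner_kind == "TLearner":
        return {arm: _fixed_or_drawn(spec, X[a == arm], rng) for arm in (0, 1)}
    return {None: _fixed_or_drawn(spec, X, rng)}


def fit_candidate(
    spec: CandidateSpec,
    train: CausalDataset,
    train_indices: np.ndarray | None = None,
    _feat_cache: dict | None = None,
) -> FittedCandidate:
    """Fit one candidate on a training set.

    ``train_indices`` (row positions in the parent dataset) are remembered as
    a fingerprint so that risk computation can refuse evaluation rows that
    the candidate has seen.
    """
    X, a, y = train.X, train.a, train.y
    kind = spec.learner_kind
    if kind in ("SftLearner", "TLearner"):
        for arm in (0, 1):
            if not (a == arm).any():
                raise ValueError(
                    f"{kind} needs both arms represented; arm {arm} is empty"
                )
    arms: dict = {}
    if spec.base_model == "ridge-on-rbf":
        key = (spec.featurization_seed, kind)
        if _feat_cache is not None and key in _feat_cache:
            feats_by_arm = _feat_cache[key]
        else:
            feats_by_arm = _draw_spec_featurizations(spec, X, a)
            if _feat_cache is not None:
                _feat_cache[key] = feats_by_arm
    if spec.base_model == "gradient-boosting":
        if kind != "SLearner":
            raise ValueError("boosting candidates are SLearner-only")
        model = HistGradientBoostingRegressor(
            learning_rate=spec.learning_rate,
            max_leaf_nodes=spec.max_leaf_nodes,
            early_stopping=False,
            random_state=spec.featurization_seed,
        )
        model.fit(np.column_stack([X, a.astype(float)]), y)
        arms["model"] = model
    elif kind == "SLearner":
        knots, h = feats_by_arm[None]
        feats = np.column_stack([rbf_features(X, knots, h), a.astype(float)])
        model = _ridge_pipeline(spec.regularization).fit(feats, y)
        arms["featurization"] = (knots, h)
        arms["model"] = model
    elif kind == "SftLearner":
        knots, h = feats_by_arm[None]
        feats = rbf_features(X, knots, h)
        arms["featurization"] = (knots, h)
        for arm in (0, 1):
            mask = a == arm
            arms[f"model{arm}"] = _ridge_pipeline(spec.regularization).fit(
                feats[mask], y[mask]
            )
    else:  # TLearner: separate featurization drawn from each arm's rows
        for arm in (0, 1):
            mask = a == arm
            knots, h = feats_by_arm[arm]
            feats = rbf_features(X[mask], knots, h)
            arms[f"featurization{arm}"] = (knots, h)
            arms[f"model{arm}"] = _ridge_pipeline(spec.regularization).fit(
                feats, y[mask]
            )
    return FittedCandidate(spec, arms, train_indices)


def _fixed_or_drawn(spec: CandidateSpec, X: np.ndarray, rng) -> tuple[np.ndarray, float]:
    if spec.knots is not None:
        return np.asarray(spec.knots, dtype=float), float(spec.bandwidth)
    return _draw_featurization(X, rng, spec.bandwidth)


def fit_family(
    specs: Sequence[CandidateSpec],
    train: CausalDataset,
    train_indices: np.ndarray | None = None,
) -> list[FittedCandidate]:
    """Fit all specs, sharing featurizations across specs that differ only
    in their penalty (same featurization seed and learner kind)."""
    cache: dict = {}
    return [
        fit_candidate(s, train, train_indices, _feat_cache=cache) for s in specs
    ]


def predict_cate(fitted: FittedCandidate, X: np.ndarray) -> np.ndarray:
    """Induced CATE tau_f(x) = f(x, 1) - f(x, 0)."""
    return fitted.predict_cate(X)


def estimate_ate(fitted: FittedCandidate, X: np.ndarray) -> float:
    """Plug-in ATE: the sample mean of the induced CATE over X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(X) == 0:
        raise ValueError("cannot estimate the ATE on an empty sample")
    return float(fitted.predict_cate(X).mean())
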