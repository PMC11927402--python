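"""Synthetic causal data from random radial-basis-function expansions.

The generator draws smooth, nonlinear response surfaces ``mu0``, ``mu1`` and a
propensity function ``e`` as random linear combinations of Gaussian kernels
centred at random knots.  A single scalar, ``overlap_strength``, scales the
propensity logit: at 0 treatment assignment is randomized, and as it grows the
treated and control covariate distributions separate (weak overlap).  Every
oracle quantity — the response surfaces, the propensity, the conditional mean
outcome ``m`` and the treatment effect ``tau`` — is carried alongside the
observed triplet ``(X, a, y)`` so that oracle risks can be evaluated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "BasisSet",
    "SimulationConfig",
    "CausalDataset",
    "sample_basis",
    "rbf_features",
    "oracle_surfaces",
    "sample_dataset",
    "make_toy_1d",
    "save_dataset",
    "load_dataset",
]

#: Half-width of the hypercube on which covariates (and knots) are sampled.
#: Bounded support keeps the Gaussian kernels informative everywhere.
COVARIATE_HALF_WIDTH = 2.0

#: The propensity logit is clamped to this magnitude so that e(x) stays
#: strictly inside (0, 1) — strong overlap always holds, though it can be made
#: arbitrarily weak (sigmoid(8) ~= 0.99966).
LOGIT_CLAMP = 8.0

#: Reference-sample size used to standardize the raw propensity score of a
#: basis, so that overlap_strength has a comparable meaning across bases.
_N_CALIBRATION = 2048


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the data-generating process.

    Parameters
    ----------
    n_samples : number of observations.
    dim : covariate dimension.
    n_knots : number of Gaussian kernels in each random basis.
    bandwidth : kernel width (same units as the covariates).
    overlap_strength : nonnegative scale of the standardized propensity
        logit; 0 gives a randomized trial, large values give weak overlap.
    effect_scale : scale of the treated-minus-control coefficient contrast,
        i.e. the ratio of effect heterogeneity to baseline heterogeneity.
    noise_sd : standard deviation of additive Gaussian outcome noise.
    logit_intercept : constant added to the propensity logit (shifts the
        treated prevalence away from ~1/2).
    share_propensity_basis : when True the propensity reuses the outcome
        knots (confounding through the same nonlinearities); by default it
        gets independently sampled knots.
    seed : master seed; expanded into independent substreams for the basis,
        the covariates, the assignment and the noise, so changing n_samples
        does not change the sampled surfaces.
    """

    n_samples: int = 1000
    dim: int = 2
    n_knots: int = 5
    bandwidth: float = 1.0
    overlap_strength: float = 1.0
    effect_scale: float = 1.0
    noise_sd: float = 0.2
    logit_intercept: float = 0.0
    share_propensity_basis: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.dim < 1 or self.n_knots < 1:
            raise ValueError("n_samples, dim and n_knots must be positive")
        if self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be > 0, got {self.bandwidth}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.overlap_strength < 0:
            raise ValueError(
                f"overlap_strength must be >= 0, got {self.overlap_strength}"
            )


@dataclass(frozen=True)
class BasisSet:
    """A sampled random-kernel basis defining one data-generating process.

    ``knots`` carry the outcome basis; ``e_knots`` the (possibly identical)
    propensity basis.  ``w0``/``w1`` are the control/treated surface
    coefficients and ``w_e`` the propensity-logit coefficients.
    ``e_center``/``e_scale`` standardize the raw propensity score over the
    covariate law so that ``overlap_strength`` is the logit's standard
    deviation, whatever the basis draw.
    """

    knots: np.ndarray  # (k, d)
    bandwidth: float
    w0: np.ndarray  # (k,)
    w1: np.ndarray  # (k,)
    e_knots: np.ndarray  # (k, d)
    w_e: np.ndarray  # (k,)
    e_center: float
    e_scale: float

    def __post_init__(self) -> None:
        k = self.knots.shape[0]
        if not (len(self.w0) == len(self.w1) == k):
            raise ValueError("outcome coefficient lengths must match knot count")
        if len(self.w_e) != self.e_knots.shape[0]:
            raise ValueError("propensity coefficients must match e_knots")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")


@dataclass
class CausalDataset:
    """Observed triplet (X, a, y), optionally with oracle surfaces.

    Simulated datasets carry all oracle columns; datasets loaded from
    observational sources may have them set to None, in which case only
    feasible risks are available downstream.
    """

    X: np.ndarray
    a: np.ndarray
    y: np.ndarray
    mu0: np.ndarray | None = None
    mu1: np.ndarray | None = None
    e: np.ndarray | None = None
    m: np.ndarray | None = None
    tau: np.ndarray | None = None
    config: SimulationConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.a = np.asarray(self.a)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.X)
        if not (len(self.a) == len(self.y) == n):
            raise ValueError("X, a, y must have the same length")
        if not np.isin(self.a, (0, 1)).all():
            raise ValueError("treatment must be binary 0/1")
        for name in ("mu0", "mu1", "e", "m", "tau"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"oracle column {name} has wrong length")
        if self.e is not None and not ((self.e > 0) & (self.e < 1)).all():
            raise ValueError("oracle propensity must lie strictly in (0, 1)")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def has_oracle(self) -> bool:
        return all(
            getattr(self, k) is not None for k in ("mu0", "mu1", "e", "m", "tau")
        )

    def subset(self, idx: np.ndarray) -> "CausalDataset":
        """Row-subset, keeping oracle columns aligned."""
        take = lambda v: None if v is None else np.asarray(v)[idx]
        return CausalDataset(
            X=self.X[idx], a=self.a[idx], y=self.y[idx],
            mu0=take(self.mu0), mu1=take(self.mu1), e=take(self.e),
            m=take(self.m), tau=take(self.tau), config=self.config,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{j}": self.X[:, j] for j in range(self.X.shape[1])}
        cols["a"] = self.a
        cols["y"] = self.y
        for name in ("mu0", "mu1", "e", "m", "tau"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


def rbf_features(X: np.ndarray, knots: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian-kernel features: entry (i, j) = exp(-||x_i - knot_j||^2 / (2 h^2)).

    Values lie in (0, 1]; a point sitting exactly on a knot maps to 1.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be > 0, got {bandwidth}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    knots = np.atleast_2d(np.asarray(knots, dtype=float))
    # squared distances via expansion; small k so memory is never a concern
    d2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ knots.T
        + (knots**2).sum(axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / (2.0 * bandwidth**2))


def _covariate_sample(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    return rng.uniform(-COVARIATE_HALF_WIDTH, COVARIATE_HALF_WIDTH, size=(n, dim))


def sample_basis(config: SimulationConfig, rng: np.random.Generator) -> BasisSet:
    """Draw one random basis: knots uniform on the covariate hypercube,
    coefficients i.i.d. standard normal, treated surface built as
    ``w1 = w0 + effect_scale * delta`` so that ``effect_scale`` directly
    controls the causal-effect-to-baseline ratio.

    The raw propensity score Phi_e @ w_e is standardized against a frozen
    reference draw from the covariate law (stored in the basis), making the
    propensity logit have unit scale before ``overlap_strength`` multiplies it.
    """
    k, d = config.n_knots, config.dim
    knots = _covariate_sample(rng, k, d)
    w0 = rng.standard_normal(k)
    delta = rng.standard_normal(k)
    w1 = w0 + config.effect_scale * delta
    if config.share_propensity_basis:
        e_knots = knots
    else:
        e_knots = _covariate_sample(rng, k, d)
    w_e = rng.standard_normal(k)
    x_ref = _covariate_sample(rng, _N_CALIBRATION, d)
    score = rbf_features(x_ref, e_knots, config.bandwidth) @ w_e
    center = float(score.mean())
    scale = float(score.std())
    if scale < 1e-12:  # degenerate basis: fall back to unscaled logit
        scale = 1.0
    return BasisSet(
        knots=knots, bandwidth=config.bandwidth, w0=w0, w1=w1,
        e_knots=e_knots, w_e=w_e, e_center=center, e_scale=scale,
    )


def oracle_surfaces(
    basis: BasisSet,
    X: np.ndarray,
    overlap_strength: float = 1.0,
    logit_intercept: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate (mu0, mu1, e) at X for a given basis.

    The propensity is ``sigmoid(overlap_strength * z(x) + intercept)`` with
    ``z`` the standardized kernel score; the logit is clamped so e never
    reaches 0 or 1 exactly.
    """
    if overlap_strength < 0:
        raise ValueError("overlap_strength must be >= 0")
    phi = rbf_features(X, basis.knots, basis.bandwidth)
    mu0 = phi @ basis.w0
    mu1 = phi @ basis.w1
    phi_e = rbf_features(X, basis.e_knots, basis.bandwidth)
    z = (phi_e @ basis.w_e - basis.e_center) / basis.e_scale
    logit = np.clip(overlap_strength * z + logit_intercept, -LOGIT_CLAMP, LOGIT_CLAMP)
    e = expit(logit)
    return mu0, mu1, e


def sample_dataset(config: SimulationConfig) -> CausalDataset:
    """Generate a full dataset: covariates, oracle surfaces, Bernoulli
    assignment and noisy outcomes.

    Uses independent substreams per source of randomness, so the sampled
    surfaces are invariant to ``n_samples``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_basis, rng_x, rng_a, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    basis = sample_basis(config, rng_basis)
    X = _covariate_sample(rng_x, config.n_samples, config.dim)
    mu0, mu1, e = oracle_surfaces(
        basis, X, config.overlap_strength, config.logit_intercept
    )
    a = (rng_a.uniform(size=config.n_samples) < e).astype(int)
    y = np.where(a == 1, mu1, mu0)
    if config.noise_sd > 0:
        y = y + config.noise_sd * rng_noise.standard_normal(config.n_samples)
    m = e * mu1 + (1.0 - e) * mu0
    tau = mu1 - mu0
    return CausalDataset(
        X=X, a=a, y=y, mu0=mu0, mu1=mu1, e=e, m=m, tau=tau, config=config
    )


def make_toy_1d(n: int, seed: int = 0, noise_sd: float = 0.05) -> CausalDataset:
    """One-covariate illustration of why factual fit and causal fit diverge.

    ``x`` plays the role of a severity score (e.g. a comorbidity index scaled
    to [0, 1]).  The treatment strongly reduces the outcome for high-severity
    patients and does essentially nothing for healthy ones, while clinicians
    preferentially treat the sick: at high x almost everyone is treated, so
    the control arm is sparse exactly where the effect is largest.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=n)
    mu0 = 0.2 + 0.6 * x**2  # baseline risk rises with severity
    tau = -0.8 * expit((x - 0.6) / 0.1)  # beneficial only when severe
    mu1 = mu0 + tau
    e = np.clip(expit(5.0 * (x - 0.45)), 1e-4, 1 - 1e-4)
    a = (rng.uniform(size=n) < e).astype(int)
    y = np.where(a == 1, mu1, mu0) + noise_sd * rng.standard_normal(n)
    m = e * mu1 + (1 - e) * mu0
    return CausalDataset(
        X=x[:, None], a=a, y=y, mu0=mu0, mu1=mu1, e=e, m=m, tau=tau
    )


def save_dataset(dataset: CausalDataset, path: str | Path) -> None:
    """Write a dataset to CSV with a JSON sidecar holding its config."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    if dataset.config is not None:
        sidecar = path.with_suffix(".config.json")
        sidecar.write_text(json.dumps(asdict(dataset.config), indent=2))


def load_dataset(path: str | Path) -> CausalDataset:
    """Read a dataset saved by :func:`save_dataset` (or any CSV with columns
    x0..x{d-1}, a, y and optional oracle columns)."""
    path = Path(path)
    df = pd.read_csv(path)
    xcols = sorted(
        (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not xcols or "a" not in df or "y" not in df:
        raise ValueError("expected columns x0..x{d-1}, a, y")
    config = None
    sidecar = path.with_suffix(".config.json")
    if sidecar.exists():
        config = SimulationConfig(**json.loads(sidecar.read_text()))
    get = lambda c: df[c].to_numpy() if c in df else None
    return CausalDataset(
        X=df[xcols].to_numpy(), a=df["a"].to_numpy(), y=df["y"].to_numpy(),
        mu0=get("mu0"), mu1=get("mu1"), e=get("e"), m=get("m"), tau=get("tau"),
        config=config,
    )
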