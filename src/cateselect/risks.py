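"""The family of causal risks for scoring candidate outcome models.

All risks are finite-sample means over an evaluation set.  The oracle
tau-risk (PEHE) needs the true CATE and is only available on simulated data.
The remaining risks are feasible: they use only observables plus nuisance
functions — the propensity e(x) and/or the conditional mean outcome m(x) —
which may be the simulator's true surfaces ("semi-oracle" flavour) or
estimates ("feasible" flavour):

- mu_risk:          factual MSE, mean (y - f(x; a))^2
- mu_risk_ipw:      factual MSE reweighted by inverse propensities
- tau_risk_ipw:     MSE of tau_f against the IPW pseudo-outcome
                    y * (a/e - (1-a)/(1-e))
- u_risk:           MSE of tau_f against the residual ratio (y - m)/(a - e)
- r_risk:           residual-on-residual loss
                    ((y - m) - (a - e) * tau_f)^2

The r_risk admits an exact population rewriting as an overlap-weighted
tau-risk plus candidate-independent Bayes residual terms; the finite-sample
version of that rewriting is :func:`reweighted_tau_risk`, used to validate
the identity by simulation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nuisances import bound_propensity

__all__ = [
    "tau_risk",
    "mu_risk",
    "mu_risk_ipw",
    "tau_risk_ipw",
    "u_risk",
    "r_risk",
    "robinson_residual",
    "reweighted_tau_risk",
    "compute_risk_table",
    "save_risk_table",
    "FEASIBLE_RISKS",
    "SEMI_ORACLE_SUFFIX",
]

#: names of the feasible risk columns in a risk table
FEASIBLE_RISKS = ("mu_risk", "mu_risk_ipw", "tau_risk_ipw", "u_risk", "r_risk")

#: suffix appended to risk columns computed with the true simulated nuisances
SEMI_ORACLE_SUFFIX = "_semi_oracle"

#: risks that divide by e or 1 - e and admit an optional propensity floor
_IPW_RISKS = ("mu_risk_ipw", "tau_risk_ipw", "u_risk")


def _check_lengths(*vecs) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(v, dtype=float) for v in vecs]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("all input vectors must have the same length")
    return tuple(arrs)


def _check_interior(e: np.ndarray) -> None:
    if (e <= 0).any() or (e >= 1).any():
        raise ValueError(
            "propensities must lie strictly in (0, 1); "
            "apply bound_propensity first"
        )


def tau_risk(tau_true: np.ndarray, tau_f: np.ndarray) -> float:
    """Oracle CATE error (PEHE): mean (tau(x) - tau_f(x))^2."""
    if tau_true is None:
        raise ValueError(
            "the oracle tau-risk needs the true CATE; on observational data "
            "use a feasible risk (r_risk, u_risk, ...)"
        )
    tau_true, tau_f = _check_lengths(tau_true, tau_f)
    return float(np.mean((tau_true - tau_f) ** 2))


def mu_risk(y: np.ndarray, f_pred: np.ndarray) -> float:
    """Factual mean squared error — the standard predictive criterion."""
    y, f_pred = _check_lengths(y, f_pred)
    return float(np.mean((y - f_pred) ** 2))


def mu_risk_ipw(
    y: np.ndarray, a: np.ndarray, f_pred: np.ndarray, e: np.ndarray
) -> float:
    """Factual MSE with inverse-propensity weights a/e + (1-a)/(1-e)."""
    y, a, f_pred, e = _check_lengths(y, a, f_pred, e)
    _check_interior(e)
    w = a / e + (1.0 - a) / (1.0 - e)
    return float(np.mean(w * (y - f_pred) ** 2))


def tau_risk_ipw(
    y: np.ndarray, a: np.ndarray, tau_f: np.ndarray, e: np.ndarray
) -> float:
    """MSE of tau_f against the Horvitz–Thompson pseudo-outcome."""
    y, a, tau_f, e = _check_lengths(y, a, tau_f, e)
    _check_interior(e)
    pseudo = y * (a / e - (1.0 - a) / (1.0 - e))
    return float(np.mean((pseudo - tau_f) ** 2))


def u_risk(
    y: np.ndarray,
    a: np.ndarray,
    tau_f: np.ndarray,
    e: np.ndarray,
    m: np.ndarray,
) -> float:
    """MSE of tau_f against the residual ratio (y - m) / (a - e).

    The denominator vanishes as e(x) approaches the realized arm, so this
    risk inherits severe variance inflation under weak overlap.
    """
    y, a, tau_f, e, m = _check_lengths(y, a, tau_f, e, m)
    _check_interior(e)
    denom = a - e
    if np.min(np.abs(denom)) < 1e-12:
        raise ValueError(
            "a - e(x) numerically zero for some rows: overlap is too weak "
            "for the U-risk; consider flooring the propensity"
        )
    return float(np.mean(((y - m) / denom - tau_f) ** 2))


def r_risk(
    y: np.ndarray,
    a: np.ndarray,
    tau_f: np.ndarray,
    e: np.ndarray,
    m: np.ndarray,
) -> float:
    """Residual-on-residual loss: mean ((y - m) - (a - e) tau_f)^2."""
    y, a, tau_f, e, m = _check_lengths(y, a, tau_f, e, m)
    return float(np.mean(((y - m) - (a - e) * tau_f) ** 2))


def robinson_residual(
    y: np.ndarray,
    a: np.ndarray,
    e: np.ndarray,
    m: np.ndarray,
    tau: np.ndarray,
) -> np.ndarray:
    """Residual of the decomposition y = m(x) + (a - e(x)) tau(x) + eps.

    With the simulator's oracle surfaces and no outcome noise the residual
    is identically zero; with noise its conditional mean given (x, a) is 0.
    """
    y, a, e, m, tau = _check_lengths(y, a, e, m, tau)
    return y - m - (a - e) * tau


def reweighted_tau_risk(
    tau_true: np.ndarray,
    tau_f: np.ndarray,
    e: np.ndarray,
    bayes_terms: float = 0.0,
) -> float:
    """Overlap-weighted tau-risk: mean e(1-e)(tau - tau_f)^2 + Bayes terms.

    This is the finite-sample version of the population identity satisfied
    by the r_risk under true nuisances.  ``bayes_terms`` holds the
    propensity-weighted Bayes residuals (sigma_B^2 terms), which vanish when
    the covariate-to-outcome link is deterministic and are independent of
    the candidate; for Gaussian noise of standard deviation s they sum to
    s^2 (the propensity weights of the two arms add to one).
    """
    tau_true, tau_f, e = _check_lengths(tau_true, tau_f, e)
    return float(np.mean(e * (1.0 - e) * (tau_true - tau_f) ** 2) + bayes_terms)


def compute_risk_table(
    candidates: Sequence,
    eval_set,
    nuisances=None,
    eval_indices: np.ndarray | None = None,
    eta: float = 1e-3,
    clip_ipw: bool = False,
) -> pd.DataFrame:
    """Score every candidate on an evaluation set with every available risk.

    Parameters
    ----------
    candidates : fitted candidates (see :mod:`cateselect.candidates`).
    eval_set : a :class:`~cateselect.simulator.CausalDataset`; when it
        carries oracle surfaces the table additionally contains the oracle
        ``tau_risk`` column and a semi-oracle flavour of each
        nuisance-dependent risk.
    nuisances : fitted :class:`~cateselect.nuisances.NuisanceEstimates`
        providing the feasible flavour; optional if the set has oracles.
    eval_indices : row positions of ``eval_set`` in the parent dataset; when
        given, candidates whose training fingerprint intersects them are
        rejected (leakage guard).
    eta, clip_ipw : optional propensity floor applied inside the risks that
        divide by e or 1-e.  Off by default: the variance inflation of the
        IPW risks under weak overlap is part of what the benchmark measures.
        The r_risk never clips.

    Returns a DataFrame indexed by candidate identifier with metadata in
    ``df.attrs``.
    """
    if nuisances is None and not eval_set.has_oracle:
        raise ValueError("need estimated nuisances or oracle surfaces")
    if eval_indices is not None:
        eval_indices = np.asarray(eval_indices)
        for c in candidates:
            ti = getattr(c, "train_indices", None)
            if ti is not None and np.intersect1d(ti, eval_indices).size:
                raise ValueError(
                    f"candidate {c.identifier!r} was trained on rows that "
                    "appear in the evaluation set"
                )
    X, a, y = eval_set.X, eval_set.a, eval_set.y

    sources: list[tuple[str, np.ndarray, np.ndarray]] = []
    if nuisances is not None:
        sources.append(("", nuisances.e_hat(X), nuisances.m_hat(X)))
    if eval_set.has_oracle:
        sources.append((SEMI_ORACLE_SUFFIX, eval_set.e, eval_set.m))

    rows = []
    index = []
    for cand in candidates:
        f_pred = cand.predict(X, a)
        tau_f = cand.predict_cate(X)
        row: dict[str, float] = {}
        if eval_set.has_oracle:
            row["tau_risk"] = tau_risk(eval_set.tau, tau_f)
        row["mu_risk"] = mu_risk(y, f_pred)  # nuisance-free
        for suffix, e_vec, m_vec in sources:
            e_ipw = bound_propensity(e_vec, eta) if clip_ipw else e_vec
            row["mu_risk_ipw" + suffix] = mu_risk_ipw(y, a, f_pred, e_ipw)
            row["tau_risk_ipw" + suffix] = tau_risk_ipw(y, a, tau_f, e_ipw)
            row["u_risk" + suffix] = u_risk(y, a, tau_f, e_ipw, m_vec)
            row["r_risk" + suffix] = r_risk(y, a, tau_f, e_vec, m_vec)
        rows.append(row)
        index.append(cand.identifier)
    table = pd.DataFrame(rows, index=pd.Index(index, name="candidate_id"))
    table.attrs["nuisance_source"] = (
        getattr(nuisances, "source", None) if nuisances is not None else "oracle-only"
    )
    table.attrs["eta"] = eta
    table.attrs["clip_ipw"] = clip_ipw
    table.attrs["n_eval"] = int(len(y))
    return table


def save_risk_table(table: pd.DataFrame, path: str | Path) -> None:
    """CSV with a candidate_id column plus a JSON metadata sidecar."""
    path = Path(path)
    table.reset_index().to_csv(path, index=False)
    meta = {k: v for k, v in table.attrs.items()}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
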