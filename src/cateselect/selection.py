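"""Train/test selection of a causal outcome model.

The procedure: split the data once (stratified on treatment), fit every
candidate and the nuisance stacks on the training side, score all candidates
with the whole risk family on the held-out side, and return the minimizer of
the configured risk.  An optional variant carves a dedicated nuisance subset
out of the training rows so that nuisances and candidates never share data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .candidates import CandidateSpec, fit_family
from .nuisances import NuisanceConfig, fit_nuisances
from .risks import compute_risk_table
from .simulator import CausalDataset

__all__ = ["SelectionConfig", "SelectionResult", "split_data", "run_selection", "select_best"]


@dataclass(frozen=True)
class SelectionConfig:
    """Configuration of one selection run.

    ``risk_name`` is any column of the risk table (e.g. ``r_risk``,
    ``mu_risk``, ``tau_risk_ipw``, a ``*_semi_oracle`` flavour, or the
    oracle ``tau_risk`` on simulated data).  ``nuisance_set`` is ``shared``
    (nuisances fitted on the full training set, alongside the candidates) or
    ``separate`` (training rows split again between nuisances and
    candidates).
    """

    train_fraction: float = 0.9
    risk_name: str = "r_risk"
    nuisance_set: str = "shared"
    seed: int = 0
    eta: float = 1e-3
    clip_ipw: bool = False
    nuisance: NuisanceConfig = field(default_factory=NuisanceConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.nuisance_set not in ("shared", "separate"):
            raise ValueError("nuisance_set must be 'shared' or 'separate'")


@dataclass
class SelectionResult:
    risk_table: pd.DataFrame
    selected_id: str
    train_indices: np.ndarray
    test_indices: np.ndarray
    nuisance_report: dict = field(default_factory=dict)


def split_data(
    dataset: CausalDataset, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test row partition, stratified on the
    treatment arm so both arms are represented on each side."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    idx = np.arange(dataset.n)
    counts = np.bincount(dataset.a, minlength=2)
    stratify = dataset.a if counts.min() >= 2 else None
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=stratify
    )
    if len(np.unique(dataset.a[train_idx])) < 2:
        raise ValueError("cannot produce a training set containing both arms")
    return np.sort(train_idx), np.sort(test_idx)


def select_best(risk_table: pd.DataFrame, risk_name: str) -> str:
    """Identifier minimizing the given risk column; ties go to the
    lexicographically smallest identifier."""
    if risk_name not in risk_table.columns:
        raise KeyError(
            f"risk {risk_name!r} not in table; available: {list(risk_table.columns)}"
        )
    col = risk_table[risk_name]
    bad = col.index[~np.isfinite(col.to_numpy())]
    if len(bad):
        raise ValueError(f"non-finite {risk_name} for candidates: {list(bad)}")
    winners = col.index[col.to_numpy() == col.min()]
    return sorted(winners)[0]


def run_selection(
    dataset: CausalDataset,
    family: Sequence[CandidateSpec],
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Execute the full selection procedure on one dataset.

    Every risk the data support is computed for every candidate — so a
    single run can be re-scored under any criterion — and the configured
    ``risk_name`` drives the returned selection.
    """
    config = config or SelectionConfig()
    if len(family) == 0:
        raise ValueError("candidate family is empty")
    train_idx, test_idx = split_data(dataset, config.train_fraction, config.seed)

    if config.nuisance_set == "separate":
        nuis_idx, cand_idx = _split_train(
            train_idx, dataset.a[train_idx],
            config.nuisance.separate_fraction, config.seed + 1,
        )
    else:
        nuis_idx = cand_idx = train_idx

    cand_train = dataset.subset(cand_idx)
    fitted = fit_family(family, cand_train, cand_idx)

    nuisances = fit_nuisances(dataset.subset(nuis_idx), config.nuisance)
    if config.nuisance_set == "separate":
        nuisances.source = "separate-nuisance-set"

    test_set = dataset.subset(test_idx)
    if config.risk_name == "tau_risk" and not dataset.has_oracle:
        raise ValueError("oracle tau_risk requires simulated (oracle) data")
    table = compute_risk_table(
        fitted, test_set, nuisances, eval_indices=test_idx,
        eta=config.eta, clip_ipw=config.clip_ipw,
    )
    selected = select_best(table, config.risk_name)
    return SelectionResult(
        risk_table=table,
        selected_id=selected,
        train_indices=train_idx,
        test_indices=test_idx,
        nuisance_report=nuisances.fit_report if nuisances is not None else {},
    )


def _split_train(train_idx, a_train, nuisance_fraction, seed):
    counts = np.bincount(a_train, minlength=2)
    stratify = a_train if counts.min() >= 2 else None
    nuis, cand = train_test_split(
        train_idx, train_size=nuisance_fraction, random_state=seed,
        stratify=stratify,
    )
    return np.sort(nuis), np.sort(cand)
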