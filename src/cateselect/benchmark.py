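"""Benchmark harness: score selection risks against the oracle CATE error.

Each benchmark run simulates many datasets with randomly drawn overlap, runs
the selection procedure once per dataset, and measures — for every risk
column of the resulting tables — how well ranking candidates by that risk
agrees with ranking them by the oracle tau-risk (Kendall correlation and its
per-dataset mean-centered version), and how much worse the selected model is
than the best available one (excess tau-risk).  Records carry two dataset
descriptors used for stratification: the normalized total-variation overlap
(NTV) and the effect-to-baseline ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .candidates import build_caussim_family
from .selection import SelectionConfig, run_selection, select_best
from .simulator import SimulationConfig, sample_dataset

__all__ = [
    "kendall_tau",
    "relative_kendall",
    "excess_tau_risk",
    "ntv_overlap",
    "effect_ratio",
    "stratify_tertiles",
    "default_config_sampler",
    "run_benchmark",
    "summarize_benchmark",
]

logger = logging.getLogger(__name__)

#: default range of the overlap knob sampled per benchmark dataset; spans
#: near-randomized trials to strongly separated arms
OVERLAP_STRENGTH_RANGE = (0.3, 3.0)


def kendall_tau(values_1: Sequence[float], values_2: Sequence[float]) -> float:
    """Tie-adjusted Kendall rank correlation between two orderings."""
    v1 = np.asarray(values_1, dtype=float)
    v2 = np.asarray(values_2, dtype=float)
    if len(v1) != len(v2):
        raise ValueError("rankings must have equal length")
    if len(v1) < 2:
        raise ValueError("need at least 2 items to rank")
    return float(kendalltau(v1, v2).statistic)


def relative_kendall(kappas: Mapping[str, float]) -> dict[str, float]:
    """Center per-risk agreements on their across-risk mean for one dataset.

    Removes the dataset-difficulty component so risks can be compared across
    heterogeneous datasets; outputs sum to zero by construction.
    """
    if len(kappas) == 0:
        raise ValueError("empty agreement map")
    mean = float(np.mean(list(kappas.values())))
    return {k: v - mean for k, v in kappas.items()}


def excess_tau_risk(risk_table: pd.DataFrame, selected_id: str) -> float:
    """Relative regret of a selection, in percent of the best achievable
    oracle tau-risk.

    Returns the absolute gap (with a warning) when the best candidate's
    tau-risk is exactly zero.
    """
    if "tau_risk" not in risk_table.columns:
        raise ValueError("risk table has no oracle tau_risk column")
    col = risk_table["tau_risk"]
    best = float(col.min())
    gap = float(col.loc[selected_id]) - best
    if best == 0.0:
        warnings.warn(
            "best candidate has zero tau-risk; returning the absolute gap",
            RuntimeWarning,
        )
        return gap
    return 100.0 * gap / best


def ntv_overlap(e: np.ndarray, prevalence: float | None = None) -> float:
    """Normalized total-variation overlap divergence, in [0, 1].

    Plug-in estimate of the total-variation distance between the treated and
    control covariate densities, written through the propensity:
    mean of 0.5 * |e_i / p - (1 - e_i) / (1 - p)| with p the treated
    prevalence (mean of e when not given).  0 means identical arms
    (randomized trial); values near 1 mean essentially disjoint supports.
    """
    e = np.asarray(e, dtype=float)
    if (e <= 0).any() or (e >= 1).any():
        raise ValueError("propensities must lie strictly in (0, 1)")
    p = float(np.mean(e)) if prevalence is None else float(prevalence)
    if not (0.0 < p < 1.0):
        raise ValueError("prevalence must lie strictly in (0, 1)")
    return float(np.mean(0.5 * np.abs(e / p - (1.0 - e) / (1.0 - p))))


def effect_ratio(
    mu0: np.ndarray,
    mu1: np.ndarray,
    denom_floor: float = 1e-8,
    return_excluded: bool = False,
):
    """Mean absolute ratio of the causal effect to the centered baseline.

    ratio_i = (mu1_i - mu0_i) / (mu0_i + mu1_i - mean(mu0 + mu1)); rows with
    a near-zero denominator are excluded (count available with
    ``return_excluded=True``).  Scale-free: multiplying both surfaces by a
    constant leaves it unchanged.
    """
    mu0 = np.asarray(mu0, dtype=float)
    mu1 = np.asarray(mu1, dtype=float)
    if mu0.shape != mu1.shape:
        raise ValueError("surface vectors must have equal length")
    s = mu0 + mu1
    denom = s - s.mean()
    keep = np.abs(denom) > denom_floor
    tau = mu1 - mu0
    if not keep.any():
        if np.allclose(tau, 0.0):
            # null effect on a flat baseline: the ratio is zero by convention
            return (0.0, int((~keep).sum())) if return_excluded else 0.0
        raise ValueError("all centered baselines are numerically zero")
    value = float(np.mean(np.abs(tau[keep] / denom[keep])))
    if return_excluded:
        return value, int((~keep).sum())
    return value


def stratify_tertiles(
    values: Sequence[float],
    labels: tuple[str, str, str] = ("strong", "medium", "weak"),
) -> np.ndarray:
    """Label each value by its tertile of the empirical distribution.

    Boundaries are half-open, lower-inclusive: [min, q1/3), [q1/3, q2/3),
    [q2/3, max].  With overlap NTV values, the first tertile (small
    divergence) is the strong-overlap stratum.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values to form tertiles")
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    out = np.where(values < q1, labels[0], np.where(values < q2, labels[1], labels[2]))
    return out


def default_config_sampler(rng: np.random.Generator, n_samples: int = 1000) -> SimulationConfig:
    """Random simulation settings: a fresh basis per dataset and an overlap
    knob drawn uniformly over a range spanning near-randomized to weakly
    overlapping regimes."""
    return SimulationConfig(
        n_samples=n_samples,
        overlap_strength=float(rng.uniform(*OVERLAP_STRENGTH_RANGE)),
        seed=int(rng.integers(2**31)),
    )


def run_benchmark(
    n_datasets: int,
    seed: int = 0,
    config_sampler: Callable[[np.random.Generator], SimulationConfig] | None = None,
    family_builder: Callable[[], list] | None = None,
    selection_config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Simulate ``n_datasets`` datasets, run selection on each, and record
    per-risk agreement with the oracle tau-risk.

    Returns one row per dataset with columns: ``ntv``, ``delta_mu``,
    ``overlap_strength`` and, for every risk column, ``kendall_<risk>``,
    ``relative_kendall_<risk>`` and ``excess_<risk>``.  Individual dataset
    failures are logged and skipped.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    config_sampler = config_sampler or default_config_sampler
    family_builder = family_builder or build_caussim_family
    selection_config = selection_config or SelectionConfig()
    rng = np.random.default_rng(seed)
    family = family_builder()
    records = []
    for i in range(n_datasets):
        sim_config = config_sampler(rng)
        sel_config = replace(selection_config, seed=int(rng.integers(2**31)))
        try:
            records.append(
                _one_record(i, sim_config, family, sel_config)
            )
        except Exception:  # noqa: BLE001 — independent datasets, keep going
            logger.exception("dataset %d failed; skipping", i)
    out = pd.DataFrame(records).set_index("dataset_id")
    out.attrs["n_requested"] = n_datasets
    out.attrs["n_failed"] = n_datasets - len(out)
    return out


def _one_record(i, sim_config, family, sel_config):
    dataset = sample_dataset(sim_config)
    result = run_selection(dataset, family, sel_config)
    table = result.risk_table
    risk_cols = [c for c in table.columns if c != "tau_risk"]
    rec: dict = {
        "dataset_id": i,
        "overlap_strength": sim_config.overlap_strength,
        "ntv": ntv_overlap(dataset.e),
        "delta_mu": effect_ratio(dataset.mu0, dataset.mu1),
    }
    kappas = {}
    for col in risk_cols:
        kappas[col] = kendall_tau(table[col], table["tau_risk"])
        rec[f"excess_{col}"] = excess_tau_risk(table, select_best(table, col))
    for col, v in kappas.items():
        rec[f"kendall_{col}"] = v
    for col, v in relative_kendall(kappas).items():
        rec[f"relative_kendall_{col}"] = v
    return rec


def summarize_benchmark(records: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range of each agreement measure per overlap
    stratum (tertiles of the realized NTV distribution)."""
    records = records.copy()
    records["overlap_stratum"] = stratify_tertiles(records["ntv"].to_numpy())
    metric_cols = [
        c for c in records.columns
        if c.startswith(("kendall_", "relative_kendall_", "excess_"))
    ]
    rows = []
    for stratum, grp in records.groupby("overlap_stratum"):
        for col in metric_cols:
            q1, med, q3 = np.percentile(grp[col], [25, 50, 75])
            rows.append(
                {
                    "overlap_stratum": stratum,
                    "metric": col,
                    "median": med,
                    "iqr_low": q1,
                    "iqr_high": q3,
                    "mean": float(grp[col].mean()),
                    "n": len(grp),
                }
            )
    return pd.DataFrame(rows)
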