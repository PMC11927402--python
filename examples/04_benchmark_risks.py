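"""Benchmark the causal risks against oracle selection on many datasets.

For each simulated dataset the selection procedure runs once, and every risk
column is scored by its Kendall agreement with the oracle CATE-error ranking
of the candidates.  A small 12-dataset run with a reduced family keeps this
example quick; the acceptance script runs the full-scale version.
"""

from cateselect import (
    SelectionConfig,
    SimulationConfig,
    build_caussim_family,
    run_benchmark,
)

records = run_benchmark(
    12,
    seed=3,
    config_sampler=lambda rng: SimulationConfig(
        n_samples=600,
        overlap_strength=float(rng.uniform(0.3, 3.0)),
        seed=int(rng.integers(2**31)),
    ),
    family_builder=lambda: build_caussim_family(n_bases=3),
    selection_config=SelectionConfig(),
)

print(f"datasets: {len(records)}; NTV range "
      f"{records['ntv'].min():.2f}-{records['ntv'].max():.2f}\n")
print(f"{'risk':>26}  {'mean Kendall':>12}  {'median excess %':>15}")
for risk in ("r_risk", "u_risk", "mu_risk", "mu_risk_ipw", "tau_risk_ipw",
             "r_risk_semi_oracle"):
    print(f"{risk:>26}  {records[f'kendall_{risk}'].mean():12.3f}"
          f"  {records[f'excess_{risk}'].median():15.1f}")

# Higher Kendall = the risk orders candidates more like the oracle CATE
# error; lower excess = the risk's argmin is closer to the best candidate.
# The semi-oracle R-risk (true nuisances) bounds what the feasible one can do.
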