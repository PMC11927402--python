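"""Run the full selection procedure on one simulated dataset.

Split 90/10, fit the 120-candidate ridge meta-learner family and the stacked
nuisances on the training side, score every candidate with every risk on the
test side, and compare selections against the oracle.
"""

from cateselect import (
    SelectionConfig,
    SimulationConfig,
    build_caussim_family,
    excess_tau_risk,
    run_selection,
    sample_dataset,
    select_best,
)

ds = sample_dataset(SimulationConfig(n_samples=1000, overlap_strength=1.0, seed=5))
family = build_caussim_family()

result = run_selection(ds, family, SelectionConfig(risk_name="r_risk", seed=0))
table = result.risk_table

print(f"candidates scored: {len(table)}; test rows: {len(result.test_indices)}")
for risk in ("r_risk", "mu_risk", "tau_risk_ipw", "tau_risk"):
    winner = select_best(table, risk)
    excess = excess_tau_risk(table, winner)
    print(f"selection by {risk:>14}: {winner:<32} excess CATE error {excess:6.1f}%")

# 'excess' is how much worse the selected model's true CATE error is than
# the best candidate's, in percent; the oracle tau_risk row is 0 by
# construction, and a good feasible risk should stay close to it.
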