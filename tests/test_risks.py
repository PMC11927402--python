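import numpy as np
import pytest

from cateselect import (
    SimulationConfig,
    compute_risk_table,
    fit_nuisances,
    kendall_tau,
    mu_risk,
    mu_risk_ipw,
    r_risk,
    reweighted_tau_risk,
    robinson_residual,
    sample_dataset,
    tau_risk,
    tau_risk_ipw,
    u_risk,
)

one = np.ones(1)


class TestHandComputedValues:
    """Single-sample worked examples, checked to machine precision."""

    def test_r_risk(self):
        # (y - m) - (a - e) tau_f = 1 - 0.75 = 0.25
        assert r_risk(2 * one, one, one, 0.25 * one, one) == 0.0625

    def test_u_risk(self):
        # (y - m)/(a - e) - tau_f = 1/0.75 - 1 = 1/3
        assert u_risk(2 * one, one, one, 0.25 * one, one) == pytest.approx(
            1.0 / 9.0, abs=1e-15
        )

    def test_tau_risk_ipw(self):
        # pseudo-outcome 2 * (1/0.5) = 4; (4 - 1)^2 = 9
        assert tau_risk_ipw(2 * one, one, one, 0.5 * one) == 9.0

    def test_mu_risk_ipw(self):
        # weight 1/0.25 = 4 times squared error 1
        assert mu_risk_ipw(2 * one, one, one, 0.25 * one) == 4.0

    def test_tau_risk_hand_sum(self):
        assert tau_risk(np.array([1.0, 1.0]), np.array([0.0, 2.0])) == 1.0

    def test_mu_risk_hand_sum(self):
        assert mu_risk(np.array([1.0, 3.0]), np.array([0.0, 0.0])) == 5.0


class TestRiskDefinitions:
    def test_tau_risk_zero_at_truth(self):
        t = np.array([0.3, -1.2, 4.0])
        assert tau_risk(t, t) == 0.0

    def test_tau_risk_requires_oracle(self):
        with pytest.raises(ValueError, match="feasible"):
            tau_risk(None, np.zeros(3))

    def test_mu_risk_ipw_doubles_at_half_propensity(self, rng):
        n = 50
        y = rng.standard_normal(n)
        f = rng.standard_normal(n)
        a = rng.integers(0, 2, n)
        e = np.full(n, 0.5)
        assert mu_risk_ipw(y, a, f, e) == pytest.approx(2 * mu_risk(y, f), rel=1e-12)

    def test_interior_propensity_enforced(self):
        with pytest.raises(ValueError, match="strictly"):
            mu_risk_ipw(one, one, one, one)

    def test_tau_risk_ipw_zero_outcome_zero_cate(self):
        z = np.zeros(4)
        assert tau_risk_ipw(z, np.array([0, 1, 0, 1]), z, np.full(4, 0.3)) == 0.0

    def test_pseudo_outcome_mean_converges_to_ate(self):
        # Horvitz–Thompson oracle: E[y(a/e - (1-a)/(1-e))] equals the ATE
        rng = np.random.default_rng(0)
        n = 10_000
        x = rng.uniform(0, 1, n)
        e = 0.2 + 0.6 * x
        a = (rng.uniform(size=n) < e).astype(int)
        mu0, mu1 = np.sin(3 * x), np.sin(3 * x) + 2.0 * x
        y = np.where(a == 1, mu1, mu0)
        pseudo = y * (a / e - (1 - a) / (1 - e))
        ate = (mu1 - mu0).mean()
        se = pseudo.std() / np.sqrt(n)
        assert abs(pseudo.mean() - ate) < 3 * se

    def test_mu_risk_ipw_matches_counterfactual_quadrature(self):
        # with oracle e the IPW factual MSE converges to the arm-balanced
        # counterfactual MSE, computed here by numerical integration
        rng = np.random.default_rng(1)
        n = 200_000
        x = rng.uniform(0, 1, n)
        e = 0.25 + 0.5 * x
        a = (rng.uniform(size=n) < e).astype(int)
        mu0, mu1 = np.cos(2 * x), np.cos(2 * x) + 1.0
        y = np.where(a == 1, mu1, mu0)
        f0, f1 = 0.2 * np.ones(n), 0.8 * np.ones(n)  # a crude candidate
        f_pred = np.where(a == 1, f1, f0)
        got = mu_risk_ipw(y, a, f_pred, e)
        grid = np.linspace(0, 1, 20_001)
        want = np.trapezoid(
            (np.cos(2 * grid) - 0.2) ** 2 + (np.cos(2 * grid) + 1.0 - 0.8) ** 2,
            grid,
        )
        assert got == pytest.approx(want, abs=0.02)

    def test_u_risk_variance_inflates_at_extreme_propensity(self):
        # same residual, same arm: shrinking e blows up the summand
        y, m, a, tf = 2 * one, one, one, one
        mild = u_risk(y, a, tf, 0.4 * one, m)
        extreme = u_risk(y, a, tf, 0.01 * one, m)
        assert extreme < mild  # a=1, e->0: denominator -> 1, term shrinks
        # the inflation occurs when e approaches the realized arm:
        inflated = u_risk(y, a, tf, 0.99 * one, m)
        assert inflated > 100 * mild

    def test_u_risk_degenerate_denominator_rejected(self):
        e = np.array([1 - 1e-13])
        with pytest.raises(ValueError, match="overlap"):
            u_risk(2 * one, one, one, e, one)


class TestRobinsonResidual:
    def test_zero_on_noiseless_oracle_inputs(self):
        ds = sample_dataset(SimulationConfig(noise_sd=0.0, seed=11))
        eps = robinson_residual(ds.y, ds.a, ds.e, ds.m, ds.tau)
        np.testing.assert_allclose(eps, 0.0, atol=1e-12)

    def test_residual_sd_matches_noise_sd(self):
        sd = 0.4
        ds = sample_dataset(
            SimulationConfig(n_samples=4000, noise_sd=sd, seed=12)
        )
        eps = robinson_residual(ds.y, ds.a, ds.e, ds.m, ds.tau)
        assert eps.std() == pytest.approx(sd, rel=0.1)


class TestReweightedTauRisk:
    def test_quarter_weight_at_half_propensity(self, rng):
        tau = rng.standard_normal(100)
        tf = rng.standard_normal(100)
        e = np.full(100, 0.5)
        got = reweighted_tau_risk(tau, tf, e)
        assert got == pytest.approx(0.25 * tau_risk(tau, tf), rel=1e-12)

    def test_r_risk_equals_quarter_tau_risk_in_rct(self):
        # constant e = 1/2 and no noise: (a - e)^2 = 1/4 exactly, so the
        # residual-on-residual loss is exactly the reweighted CATE error
        ds = sample_dataset(
            SimulationConfig(noise_sd=0.0, overlap_strength=0.0, seed=13)
        )
        tf = ds.tau + np.sin(ds.X[:, 0])  # an arbitrary imperfect candidate
        got = r_risk(ds.y, ds.a, tf, ds.e, ds.m)
        assert got == pytest.approx(0.25 * tau_risk(ds.tau, tf), rel=1e-12)

    def test_identity_holds_to_sampling_tolerance(self):
        # the residual-on-residual loss is a Bernoulli Monte-Carlo draw of
        # the overlap-weighted CATE error; absolute gap <= 5/sqrt(n) * scale^2
        rng = np.random.default_rng(14)
        for seed in range(20):
            cfg = SimulationConfig(
                n_samples=2000, noise_sd=0.0, seed=seed,
                overlap_strength=float(rng.uniform(0.3, 3.0)),
            )
            ds = sample_dataset(cfg)
            tf = ds.tau + rng.standard_normal(ds.n) * 0.5
            gap = abs(
                r_risk(ds.y, ds.a, tf, ds.e, ds.m)
                - reweighted_tau_risk(ds.tau, tf, ds.e)
            )
            scale2 = np.mean((ds.tau - tf) ** 2)
            assert gap <= 5.0 / np.sqrt(ds.n) * scale2

    def test_candidate_differences_are_exactly_weighted(self, rng):
        # Bayes terms are candidate-independent: differences cancel them
        tau = rng.standard_normal(50)
        e = rng.uniform(0.1, 0.9, 50)
        tf1, tf2 = rng.standard_normal(50), rng.standard_normal(50)
        bayes = 1.234
        d = reweighted_tau_risk(tau, tf1, e, bayes) - reweighted_tau_risk(
            tau, tf2, e, bayes
        )
        want = np.mean(e * (1 - e) * ((tau - tf1) ** 2 - (tau - tf2) ** 2))
        assert d == pytest.approx(want, rel=1e-12)


class TestRiskTable:
    def test_full_family_table(self, fitted_small_family, default_dataset):
        fitted, train_idx, test_idx = fitted_small_family
        nu = fit_nuisances(default_dataset.subset(train_idx))
        table = compute_risk_table(
            fitted, default_dataset.subset(test_idx), nu, eval_indices=test_idx
        )
        assert len(table) == len(fitted)
        assert np.isfinite(table.to_numpy()).all()
        assert (table.to_numpy() >= 0).all()
        for col in ("tau_risk", "r_risk", "r_risk_semi_oracle", "u_risk"):
            assert col in table.columns

    def test_leakage_rejected(self, fitted_small_family, default_dataset):
        fitted, train_idx, _ = fitted_small_family
        with pytest.raises(ValueError, match="trained on rows"):
            compute_risk_table(
                fitted,
                default_dataset.subset(train_idx[:50]),
                None,
                eval_indices=train_idx[:50],
            )

    def test_semi_oracle_tracks_feasible_r_risk(
        self, fitted_small_family, default_dataset
    ):
        fitted, train_idx, test_idx = fitted_small_family
        nu = fit_nuisances(default_dataset.subset(train_idx))
        table = compute_risk_table(fitted, default_dataset.subset(test_idx), nu)
        assert kendall_tau(table["r_risk"], table["r_risk_semi_oracle"]) > 0

    def test_risks_invariant_to_row_permutation(
        self, fitted_small_family, default_dataset, rng
    ):
        fitted, train_idx, test_idx = fitted_small_family
        nu = fit_nuisances(default_dataset.subset(train_idx))
        test = default_dataset.subset(test_idx)
        perm = rng.permutation(test.n)
        t1 = compute_risk_table(fitted[:3], test, nu)
        t2 = compute_risk_table(fitted[:3], test.subset(perm), nu)
        np.testing.assert_allclose(t1.to_numpy(), t2.to_numpy(), rtol=1e-10)

    def test_requires_some_nuisance_source(self):
        ds = sample_dataset(SimulationConfig(seed=15))
        bare = ds.subset(np.arange(ds.n))
        bare.mu0 = None
        with pytest.raises(ValueError, match="nuisance"):
            compute_risk_table([], bare, None)
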