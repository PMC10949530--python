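"""Gibbs-sampler GBLUP against closed-form and limiting-case oracles."""

import numpy as np
import pandas as pd
import pytest

from mmgp import gblup, synthetic
from mmgp.kinship import RelationshipMatrix


def _obs(pheno):
    return list(zip(pheno["environment"], pheno["line"]))


class TestConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            gblup.GBLUPConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            gblup.GBLUPConfig(thin=0)
        with pytest.raises(ValueError):
            gblup.GBLUPConfig(R2=1.5)


class TestSampler:
    def test_noiseless_data_is_interpolated(self):
        """With a tight residual prior, noiseless phenotypes are reproduced."""
        cfg = synthetic.SimConfig(J=60, I=3, M=400, sigma_e2=1e-8, seed=4)
        met = synthetic.simulate_met(cfg)
        fit = gblup.fit_gblup(
            met.phenotypes,
            met.truth["G"],
            gblup.GBLUPConfig(n_iter=5000, burn_in=2000, thin=4, seed=1, R2=0.99),
        )
        pred = gblup.predict(fit, _obs(met.phenotypes))
        assert np.corrcoef(pred, met.phenotypes["value"])[0, 1] > 0.999

    def test_ridge_closed_form_with_identity_kinship(self):
        """G = I and no interaction reduces the model to ridge regression."""
        rng = np.random.default_rng(8)
        J = 80
        line_ids = [f"L{j}" for j in range(J)]
        y = 3.0 + rng.standard_normal(J) + 0.5 * rng.standard_normal(J)
        pheno = pd.DataFrame(
            {"environment": "E0", "line": line_ids, "value": y}
        )
        G = RelationshipMatrix(np.eye(J), line_ids)
        fit = gblup.fit_gblup(
            pheno, G,
            gblup.GBLUPConfig(n_iter=4000, burn_in=1000, thin=3, seed=2),
            include_gE=False, include_env=False,
        )
        lam = fit.var_e / fit.var_g
        g_ridge = (y - fit.mu) / (1.0 + lam)
        rel = np.linalg.norm(fit.g.to_numpy() - g_ridge) / np.linalg.norm(g_ridge)
        assert rel < 0.05

    def test_posterior_samples_shape_and_positivity(self, small_met):
        cfg = gblup.GBLUPConfig(n_iter=400, burn_in=100, thin=3, seed=0)
        fit = gblup.fit_gblup(small_met.phenotypes, small_met.truth["G"], cfg)
        n_expected = len(range(cfg.burn_in, cfg.n_iter, cfg.thin))
        assert fit.n_samples == n_expected
        assert (fit.posterior_samples["var_g"] > 0).all()
        assert (fit.posterior_samples["var_e"] > 0).all()

    def test_two_chains_agree_on_predictions(self, small_met):
        pheno, G = small_met.phenotypes, small_met.truth["G"]
        cfg = dict(n_iter=6000, burn_in=2000, thin=4)
        pA = gblup.predict(
            gblup.fit_gblup(pheno, G, gblup.GBLUPConfig(seed=11, **cfg)), _obs(pheno)
        )
        pB = gblup.predict(
            gblup.fit_gblup(pheno, G, gblup.GBLUPConfig(seed=12, **cfg)), _obs(pheno)
        )
        rel_rms = np.sqrt(np.mean((pA - pB) ** 2)) / np.std(pheno["value"])
        assert rel_rms < 0.02

    def test_unknown_line_raises(self, small_met):
        pheno = small_met.phenotypes.copy()
        pheno.loc[0, "line"] = "NOT_A_LINE"
        with pytest.raises(KeyError):
            gblup.fit_gblup(pheno, small_met.truth["G"], gblup.GBLUPConfig(n_iter=10, burn_in=0))


class TestClosedForm:
    def test_strong_shrinkage_limit_gives_environment_means(self, small_met):
        pheno, G = small_met.phenotypes, small_met.truth["G"]
        cf = gblup.blup_closed_form(pheno, G, sigma_g2=1e-9, sigma_e2=1.0)
        assert np.max(np.abs(cf["g"].to_numpy())) < 1e-6
        env_means = pheno.groupby("environment")["value"].mean()
        for env, mean in env_means.items():
            assert cf["mu"] + cf["env_effects"][env] == pytest.approx(mean, abs=1e-6)

    def test_two_line_toy_against_direct_solve(self):
        line_ids = ["a", "b"]
        y = np.array([1.0, 3.0])
        pheno = pd.DataFrame({"environment": "E0", "line": line_ids, "value": y})
        G = RelationshipMatrix(np.eye(2), line_ids)
        cf = gblup.blup_closed_form(pheno, G, sigma_g2=2.0, sigma_e2=1.0)
        # Henderson system: [n  1'; 1  I(1+lam)] [mu; g] = [sum y; y]
        lam = 0.5
        A = np.array([[2.0, 1.0, 1.0], [1.0, 1.0 + lam, 0.0], [1.0, 0.0, 1.0 + lam]])
        sol = np.linalg.solve(A, np.array([y.sum(), y[0], y[1]]))
        assert cf["mu"] == pytest.approx(sol[0], abs=1e-10)
        np.testing.assert_allclose(cf["g"].to_numpy(), sol[1:], atol=1e-10)

    def test_residuals_orthogonal_to_fixed_design(self, small_met):
        pheno, G = small_met.phenotypes, small_met.truth["G"]
        cf = gblup.blup_closed_form(pheno, G, sigma_g2=1.0, sigma_e2=1.0, sigma_gE2=0.5)
        X, _ = cf["design"]
        resid = pheno["value"].to_numpy() - cf["fitted"]
        np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-7)

    def test_label_invariance(self, small_met):
        """Permuting line order in G and phenotypes permutes outputs exactly."""
        pheno, G = small_met.phenotypes, small_met.truth["G"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(G.n_lines)
        G_p = RelationshipMatrix(
            G.G[np.ix_(perm, perm)], [G.line_ids[i] for i in perm]
        )
        cf = gblup.blup_closed_form(pheno, G, sigma_g2=1.0, sigma_e2=1.0)
        cf_p = gblup.blup_closed_form(pheno, G_p, sigma_g2=1.0, sigma_e2=1.0)
        np.testing.assert_allclose(
            cf["g"].sort_index().to_numpy(),
            cf_p["g"].sort_index().to_numpy(),
            atol=1e-8,
        )


class TestPredict:
    def test_g_only_predictions_constant_across_environments(self, small_met):
        fit = gblup.fit_gblup(
            small_met.phenotypes,
            small_met.truth["G"],
            gblup.GBLUPConfig(n_iter=300, burn_in=100, thin=2, seed=0),
            include_gE=False,
            include_env=False,
        )
        line = small_met.line_ids[0]
        preds = gblup.predict(fit, [(e, line) for e in small_met.env_ids])
        assert np.ptp(preds) == 0.0

    def test_unrelated_line_shrinks_to_environment_mean(self):
        """A line with no kinship to training lines predicts at mu + E."""
        J = 30
        line_ids = [f"L{j}" for j in range(J)] + ["stranger"]
        G = np.eye(J + 1)
        rng = np.random.default_rng(3)
        y = 5.0 + rng.standard_normal(J)
        pheno = pd.DataFrame(
            {"environment": "E0", "line": line_ids[:J], "value": y}
        )
        cf = gblup.blup_closed_form(
            pheno, RelationshipMatrix(G, line_ids), sigma_g2=1.0, sigma_e2=1.0
        )
        pred = cf["predict"]([("E0", "stranger")])
        assert pred[0] == pytest.approx(cf["mu"], abs=1e-10)

    def test_unknown_line_raises(self, small_met):
        fit = gblup.fit_gblup(
            small_met.phenotypes,
            small_met.truth["G"],
            gblup.GBLUPConfig(n_iter=50, burn_in=10, thin=1, seed=0),
        )
        with pytest.raises(KeyError):
            gblup.predict(fit, [("E0", "nope")])
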