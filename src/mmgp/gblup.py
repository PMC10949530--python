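"""Bayesian GBLUP mixed model fitted by Gibbs sampling.

The phenotype of line j in environment i is modeled as

    Y_ij = mu + E_i + g_j + gE_ij + eps_ij

with flat priors on the general mean and environment effects, line effects
g ~ N(0, sigma_g2 * G), interaction effects gE ~ N(0, sigma_gE2 * (I ⊗ G))
and iid residuals.  Each variance carries a scaled-inverse-chi-squared prior
whose scale is mode-matched to an a-priori variance partition of var(y)
(fraction R2 split equally among the genetic terms, 1 - R2 to the residual).

The sampler works in the eigenbasis of G: one symmetric eigendecomposition is
reused for the line-effect update and for each per-environment interaction
block, which exploits the I ⊗ G structure without ever forming an
(I·J) x (I·J) array.  ``blup_closed_form`` solves Henderson's mixed-model
equations at fixed variance ratios and serves as a deterministic oracle for
the sampler.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.linalg

from .kinship import RelationshipMatrix

__all__ = ["GBLUPConfig", "GBLUPModel", "fit_gblup", "blup_closed_form", "predict"]


@dataclasses.dataclass
class GBLUPConfig:
    """Gibbs chain and prior settings (BGLR-style defaults)."""

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    df0: float = 5.0
    R2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.df0 <= 0:
            raise ValueError("df0 must be positive")
        if not 0.0 < self.R2 < 1.0:
            raise ValueError("R2 must lie in (0, 1)")


@dataclasses.dataclass
class GBLUPModel:
    """Posterior summaries and retained draws of the fitted mixed model."""

    mu: float
    env_effects: dict[str, float]  # sum-to-zero coding; empty if env excluded
    g: pd.Series  # posterior-mean line effects, indexed by line id
    gE: pd.DataFrame | None  # environments x lines posterior means, or None
    var_g: float
    var_gE: float | None
    var_e: float
    posterior_samples: dict[str, np.ndarray]
    include_env: bool
    include_gE: bool
    line_ids: list[str]
    env_ids: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.posterior_samples["var_e"])


def _prior_scales(y: np.ndarray, df0: float, R2: float, n_terms: int) -> tuple[float, float]:
    """Mode-matched scaled-inverse-chi-squared prior scales (genetic, residual).

    The prior mode df0*S0/(df0+2) equals the target variance share, i.e.
    S0 = target * (df0 + 2) / df0.
    """
    vy = float(np.var(y))
    s_gen = vy * R2 / max(n_terms, 1) * (df0 + 2.0) / df0
    s_res = vy * (1.0 - R2) * (df0 + 2.0) / df0
    return s_gen, s_res


def _sample_scaled_inv_chi2(rng, df: float, scale_sum: float) -> float:
    """Draw from the scaled-inverse-chi-squared full conditional.

    scale_sum is SS + df0*S0; the draw is scale_sum / chi2(df).
    """
    return scale_sum / rng.chisquare(df)


def _design(obs_env: np.ndarray, obs_line: np.ndarray, n_env: int, n_lines: int,
            include_env: bool) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Fixed-effect design (intercept + env contrasts) and index helpers."""
    n = len(obs_env)
    if include_env and n_env >= 2:
        X = np.zeros((n, n_env))
        X[:, 0] = 1.0
        for i in range(1, n_env):
            X[obs_env == i, i] = 1.0  # treatment coding, env 0 reference
    else:
        X = np.ones((n, 1))
    env_rows = [np.flatnonzero(obs_env == i) for i in range(n_env)]
    return X, np.arange(n), env_rows


def fit_gblup(
    y: pd.DataFrame,
    G: RelationshipMatrix,
    config: GBLUPConfig | None = None,
    include_gE: bool = True,
    include_env: bool = True,
) -> GBLUPModel:
    """Fit the mixed model by Gibbs sampling.

    ``y`` is a long table with columns ``environment``, ``line`` and ``value``.
    Every observed line must be indexed in ``G``.  ``include_env=False`` drops
    the environment main effects (G-only predictor); ``include_gE=False``
    drops the interaction term (E+G predictor).  Reproducible given
    ``config.seed``.
    """
    if config is None:
        config = GBLUPConfig()
    rng = np.random.default_rng(config.seed)

    env_ids = sorted(y["environment"].unique())
    line_ids = list(G.line_ids)
    line_pos = {line: j for j, line in enumerate(line_ids)}
    unknown = set(y["line"]) - set(line_ids)
    if unknown:
        raise KeyError(f"lines not indexed in G: {sorted(unknown)[:5]}")
    if include_env and len(env_ids) < 2:
        raise ValueError("environment effects require >= 2 environments")

    obs_env = np.array([env_ids.index(e) for e in y["environment"]])
    obs_line = np.array([line_pos[l] for l in y["line"]])
    yv = y["value"].to_numpy(dtype=float)
    n = len(yv)
    I, J = len(env_ids), len(line_ids)

    # eigenbasis of G, reused for every genomic update
    d, U = scipy.linalg.eigh(G.G)
    if d.min() <= 0:
        raise scipy.linalg.LinAlgError(
            "G is singular; add diagonal jitter before fitting"
        )

    X, _, env_rows = _design(obs_env, obs_line, I, J, include_env)
    XtX = X.T @ X
    XtX_chol = scipy.linalg.cho_factor(XtX)

    # Z_L' Z_L is diagonal with per-line observation counts; in the eigenbasis
    # the cross-product becomes U' diag(counts) U
    counts = np.bincount(obs_line, minlength=J).astype(float)
    M_g = (U.T * counts) @ U
    M_gE = []
    if include_gE:
        for i in range(I):
            ind = np.zeros(J)
            np.add.at(ind, obs_line[env_rows[i]], 1.0)
            M_gE.append((U.T * ind) @ U)

    n_terms = 1 + int(include_gE)
    s_gen, s_res = _prior_scales(yv, config.df0, config.R2, n_terms)
    df0 = config.df0

    # state
    beta = np.zeros(X.shape[1])
    a = np.zeros(J)  # g in eigen coordinates, g = U a
    aE = np.zeros((I, J)) if include_gE else None
    var_g = float(np.var(yv)) * config.R2 / n_terms
    var_gE = var_g if include_gE else None
    var_e = float(np.var(yv)) * (1.0 - config.R2)

    g_obs = np.zeros(n)
    gE_obs = np.zeros(n)
    resid = yv - X @ beta - g_obs - gE_obs

    keep = [t for t in range(config.n_iter) if t >= config.burn_in
            and (t - config.burn_in) % config.thin == 0]
    n_keep = len(keep)
    samples = {
        "mu": np.zeros(n_keep),
        "beta": np.zeros((n_keep, X.shape[1])),
        "g": np.zeros((n_keep, J)),
        "var_g": np.zeros(n_keep),
        "var_e": np.zeros(n_keep),
    }
    if include_gE:
        samples["gE"] = np.zeros((n_keep, I, J))
        samples["var_gE"] = np.zeros(n_keep)
    keep_set = {t: s for s, t in enumerate(keep)}

    Ut = U.T
    for t in range(config.n_iter):
        # --- fixed effects (flat prior) ---
        r_f = resid + X @ beta
        mean_beta = scipy.linalg.cho_solve(XtX_chol, X.T @ r_f)
        z = rng.standard_normal(X.shape[1])
        L_xtx = scipy.linalg.cholesky(XtX / var_e, lower=True)
        beta = mean_beta + scipy.linalg.solve_triangular(L_xtx.T, z, lower=False)
        resid = r_f - X @ beta

        # --- line effects in the eigenbasis ---
        r_g = resid + g_obs
        b = Ut @ np.bincount(obs_line, weights=r_g, minlength=J) / var_e
        P = M_g / var_e + np.diag(1.0 / (d * var_g))
        c_low = scipy.linalg.cholesky(P, lower=True)
        mean_a = scipy.linalg.cho_solve((c_low, True), b)
        a = mean_a + scipy.linalg.solve_triangular(
            c_low.T, rng.standard_normal(J), lower=False
        )
        g_lines = U @ a
        g_obs = g_lines[obs_line]
        resid = r_g - g_obs

        # --- interaction effects, one G-block per environment ---
        if include_gE:
            r_gE = resid + gE_obs
            gE_lines = np.zeros((I, J))
            for i in range(I):
                rows = env_rows[i]
                bi = np.zeros(J)
                np.add.at(bi, obs_line[rows], r_gE[rows])
                bi = Ut @ bi / var_e
                Pi = M_gE[i] / var_e + np.diag(1.0 / (d * var_gE))
                ci = scipy.linalg.cholesky(Pi, lower=True)
                mean_ai = scipy.linalg.cho_solve((ci, True), bi)
                aE[i] = mean_ai + scipy.linalg.solve_triangular(
                    ci.T, rng.standard_normal(J), lower=False
                )
                gE_lines[i] = U @ aE[i]
            gE_obs = gE_lines[obs_env, obs_line]
            resid = r_gE - gE_obs

        # --- variance components ---
        ss_g = float(np.sum(a**2 / d))
        var_g = _sample_scaled_inv_chi2(rng, df0 + J, ss_g + df0 * s_gen)
        if include_gE:
            ss_gE = float(np.sum(aE**2 / d[np.newaxis, :]))
            var_gE = _sample_scaled_inv_chi2(rng, df0 + I * J, ss_gE + df0 * s_gen)
        var_e = _sample_scaled_inv_chi2(
            rng, df0 + n, float(resid @ resid) + df0 * s_res
        )

        if t in keep_set:
            s = keep_set[t]
            samples["beta"][s] = beta
            samples["g"][s] = g_lines
            samples["var_g"][s] = var_g
            samples["var_e"][s] = var_e
            if include_gE:
                samples["gE"][s] = gE_lines
                samples["var_gE"][s] = var_gE

    # re-express fixed effects: mu + sum-to-zero environment effects
    beta_mean = samples["beta"].mean(axis=0)
    if include_env and I >= 2:
        env_means = np.concatenate([[beta_mean[0]], beta_mean[0] + beta_mean[1:]])
        mu_hat = float(np.mean(env_means))
        env_eff = {env: float(env_means[i] - mu_hat) for i, env in enumerate(env_ids)}
        samples["mu"] = samples["beta"][:, 0] + np.mean(
            np.concatenate(
                [np.zeros((n_keep, 1)), samples["beta"][:, 1:]], axis=1
            ),
            axis=1,
        )
    else:
        mu_hat = float(beta_mean[0])
        env_eff = {}
        samples["mu"] = samples["beta"][:, 0]

    g_mean = pd.Series(samples["g"].mean(axis=0), index=line_ids)
    gE_mean = None
    var_gE_mean = None
    if include_gE:
        gE_mean = pd.DataFrame(
            samples["gE"].mean(axis=0), index=env_ids, columns=line_ids
        )
        var_gE_mean = float(samples["var_gE"].mean())

    return GBLUPModel(
        mu=mu_hat,
        env_effects=env_eff,
        g=g_mean,
        gE=gE_mean,
        var_g=float(samples["var_g"].mean()),
        var_gE=var_gE_mean,
        var_e=float(samples["var_e"].mean()),
        posterior_samples=samples,
        include_env=include_env and I >= 2,
        include_gE=include_gE,
        line_ids=line_ids,
        env_ids=env_ids,
    )


def predict(model: GBLUPModel, obs: list[tuple[str, str]]) -> np.ndarray:
    """Posterior-mean predictions for (environment, line) pairs.

    y_hat = mu + E_i + g_j + gE_ij, omitting any term absent from the fitted
    predictor.  An environment unseen in training contributes 0 (effects are
    in sum-to-zero coding, so this is the average-environment prediction);
    a line must be indexed in G.
    """
    out = np.zeros(len(obs))
    for r, (env, line) in enumerate(obs):
        if line not in model.g.index:
            raise KeyError(f"unknown line {line!r}")
        val = model.mu + model.g[line]
        if model.include_env:
            val += model.env_effects.get(env, 0.0)
        if model.include_gE and model.gE is not None and env in model.gE.index:
            val += model.gE.loc[env, line]
        out[r] = val
    return out


def blup_closed_form(
    y: pd.DataFrame,
    G: RelationshipMatrix,
    sigma_g2: float,
    sigma_e2: float,
    sigma_gE2: float = 0.0,
    include_env: bool = True,
) -> dict:
    """Henderson mixed-model-equation solve at fixed variance components.

    Deterministic oracle for the Gibbs sampler: exact GLS/BLUP estimates of
    (mu, E, g, gE) given the variance ratios.  Returns a dict with ``mu``,
    ``env_effects``, ``g`` (Series), ``gE`` (DataFrame or None) and a
    ``predict(obs)`` closure mirroring :func:`predict`.
    """
    if sigma_g2 <= 0 or sigma_e2 <= 0 or sigma_gE2 < 0:
        raise ValueError("sigma_g2 and sigma_e2 must be positive, sigma_gE2 >= 0")
    env_ids = sorted(y["environment"].unique())
    line_ids = list(G.line_ids)
    line_pos = {line: j for j, line in enumerate(line_ids)}
    obs_env = np.array([env_ids.index(e) for e in y["environment"]])
    obs_line = np.array([line_pos[l] for l in y["line"]])
    yv = y["value"].to_numpy(dtype=float)
    n = len(yv)
    I, J = len(env_ids), len(line_ids)
    use_env = include_env and I >= 2
    use_gE = sigma_gE2 > 0

    X, _, env_rows = _design(obs_env, obs_line, I, J, use_env)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError(
            "rank-deficient fixed-effect design; drop one environment as reference"
        )

    Z_L = np.zeros((n, J))
    Z_L[np.arange(n), obs_line] = 1.0
    blocks = [X, Z_L]
    if use_gE:
        Z_EL = np.zeros((n, I * J))
        Z_EL[np.arange(n), obs_env * J + obs_line] = 1.0
        blocks.append(Z_EL)
    W = np.concatenate(blocks, axis=1)

    Ginv = np.linalg.inv(G.G)
    lam_g = sigma_e2 / sigma_g2
    dim = W.shape[1]
    C = W.T @ W
    C[p : p + J, p : p + J] += lam_g * Ginv
    if use_gE:
        lam_gE = sigma_e2 / sigma_gE2
        for i in range(I):
            sl = slice(p + J + i * J, p + J + (i + 1) * J)
            C[sl, sl] += lam_gE * Ginv
    rhs = W.T @ yv
    sol = np.linalg.solve(C, rhs)

    beta = sol[:p]
    g_hat = sol[p : p + J]
    if use_env:
        env_means = np.concatenate([[beta[0]], beta[0] + beta[1:]])
        mu_hat = float(np.mean(env_means))
        env_eff = {env: float(env_means[i] - mu_hat) for i, env in enumerate(env_ids)}
    else:
        mu_hat = float(beta[0])
        env_eff = {}
    g_series = pd.Series(g_hat, index=line_ids)
    gE_frame = None
    if use_gE:
        gE_frame = pd.DataFrame(
            sol[p + J :].reshape(I, J), index=env_ids, columns=line_ids
        )

    def _predict(obs: list[tuple[str, str]]) -> np.ndarray:
        vals = np.zeros(len(obs))
        for r, (env, line) in enumerate(obs):
            v = mu_hat + g_series[line]
            if use_env:
                v += env_eff.get(env, 0.0)
            if gE_frame is not None and env in gE_frame.index:
                v += gE_frame.loc[env, line]
            vals[r] = v
        return vals

    fitted = _predict(list(zip(y["environment"], y["line"])))
    return {
        "mu": mu_hat,
        "env_effects": env_eff,
        "g": g_series,
        "gE": gE_frame,
        "fitted": fitted,
        "predict": _predict,
        "design": (X, W),
    }
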