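"""Synthetic multi-environment trial (MET) generator.

Phenotypes follow the additive mixed model

    Y_ij = mu + E_i + g_j + gE_ij + eps_ij

with line effects g ~ N(0, sigma_g2 * G) drawn through the triangular factor
of the marker-derived genomic relationship matrix G, interaction effects drawn
independently per environment with covariance sigma_gE2 * G (exactly the
I ⊗ G block-diagonal structure — no cross-environment genetic correlation),
random environment main effects, and iid Gaussian noise.  The realized truth
(all effects and variance components) is recorded so parameter-recovery and
prediction tests can score estimators against it.

Defaults describe a desk-scale wheat-like trial: 300 lines, 3 environments,
2000 markers with allele frequencies in (0.1, 0.9), variance components
(sigma_g2, sigma_gE2, sigma_e2) = (1.0, 0.5, 1.0) and a grand mean of 10 so
phenotypes are strictly positive (mean-normalized error is well defined).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import kinship
from .genotype_io import MarkerMatrix, RECODED

__all__ = [
    "SimConfig",
    "SimulatedMET",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_met",
    "realized_h2",
]


@dataclasses.dataclass
class SimConfig:
    J: int = 300  # lines
    I: int = 3  # environments
    M: int = 2000  # markers
    freq_range: tuple[float, float] = (0.1, 0.9)
    mu: float = 10.0
    env_effect_sd: float = 1.0
    sigma_g2: float = 1.0
    sigma_gE2: float = 0.5
    sigma_e2: float = 1.0
    missing_pheno_fraction: float = 0.0
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.J, self.I, self.M) < 1:
            raise ValueError("J, I and M must be positive")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele frequencies must lie inside (0, 1)")
        for name in ("sigma_g2", "sigma_gE2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.missing_pheno_fraction < 1.0:
            raise ValueError("missing_pheno_fraction must lie in [0, 1)")


@dataclasses.dataclass
class SimulatedMET:
    markers: MarkerMatrix
    phenotypes: pd.DataFrame  # columns: environment, line, trait, value
    truth: dict
    config: SimConfig

    @property
    def env_ids(self) -> list[str]:
        return self.truth["env_ids"]

    @property
    def line_ids(self) -> list[str]:
        return list(self.markers.line_ids)


def simulate_genotypes(cfg: SimConfig) -> MarkerMatrix:
    """Draw biallelic genotypes: dosage ~ Binomial(2, p_k), mapped to {-1, 0, +1}."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.freq_range
    p = rng.uniform(lo, hi, size=cfg.M)
    dosage = rng.binomial(2, p[np.newaxis, :], size=(cfg.J, cfg.M))
    values = dosage.astype(float) - 1.0
    line_ids = [f"L{j:04d}" for j in range(cfg.J)]
    marker_ids = [f"M{k:05d}" for k in range(cfg.M)]
    return MarkerMatrix(values, line_ids, marker_ids, coding_tag=RECODED)


def simulate_phenotypes(markers: MarkerMatrix, cfg: SimConfig) -> SimulatedMET:
    """Assemble Y = mu + E + g + gE + eps on a complete I x J design.

    Effects with genomic covariance are drawn through the triangular factor of
    G computed from ``markers``; the interaction effect for each environment
    is an independent draw with covariance sigma_gE2 * G.  A fraction of
    phenotype rows can be dropped at random to emulate unbalanced trials.
    The derived phenotype stream is independent of the genotype stream so the
    same marker set can host replicate trials.
    """
    if np.isnan(markers.values).any():
        raise ValueError("markers must be imputed (no missing) before simulation")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 83251]))
    # canonical (sorted) line order: the simulation depends on line labels,
    # not on the row order of the marker matrix
    order = np.argsort(np.asarray(markers.line_ids, dtype=object))
    line_ids = [markers.line_ids[i] for i in order]
    canon = MarkerMatrix(
        markers.values[order], line_ids, list(markers.marker_ids), coding_tag=RECODED
    )
    G = kinship.compute_grm(canon)
    L = kinship.chol_factor(G, kinship.GRAM).F
    J, I = cfg.J, cfg.I

    g = np.sqrt(cfg.sigma_g2) * (L @ rng.standard_normal(J))
    gE = np.sqrt(cfg.sigma_gE2) * (L @ rng.standard_normal((J, I))).T  # (I, J)
    env_effects = cfg.env_effect_sd * rng.standard_normal(I)
    eps = np.sqrt(cfg.sigma_e2) * rng.standard_normal((I, J))

    env_ids = [f"E{i}" for i in range(I)]
    Y = cfg.mu + env_effects[:, None] + g[None, :] + gE + eps

    records = []
    for i, env in enumerate(env_ids):
        for j, line in enumerate(line_ids):
            records.append((env, line, cfg.trait, Y[i, j]))
    pheno = pd.DataFrame(records, columns=["environment", "line", "trait", "value"])
    if cfg.missing_pheno_fraction > 0:
        n_keep = int(round(len(pheno) * (1.0 - cfg.missing_pheno_fraction)))
        keep = rng.choice(len(pheno), size=n_keep, replace=False)
        pheno = pheno.iloc[np.sort(keep)].reset_index(drop=True)

    truth = {
        "mu": cfg.mu,
        "env_ids": env_ids,
        "line_ids": line_ids,
        "env_effects": env_effects,
        "g": g,
        "gE": gE,
        "sigma_g2": cfg.sigma_g2,
        "sigma_gE2": cfg.sigma_gE2,
        "sigma_e2": cfg.sigma_e2,
        "G": G,
    }
    return SimulatedMET(markers=markers, phenotypes=pheno, truth=truth, config=cfg)


def simulate_met(cfg: SimConfig) -> SimulatedMET:
    """Convenience: genotypes then phenotypes from one config."""
    return simulate_phenotypes(simulate_genotypes(cfg), cfg)


def realized_h2(met: SimulatedMET) -> float:
    """Realized narrow-sense heritability of the simulated draws.

    var(g) over the within-environment phenotypic variance var(Y - mu - E_i),
    averaged across environments.
    """
    g = met.truth["g"]
    mu = met.truth["mu"]
    env_effects = met.truth["env_effects"]
    var_g = float(np.var(g))
    ratios = []
    pheno = met.phenotypes
    for i, env in enumerate(met.env_ids):
        vals = pheno.loc[pheno["environment"] == env, "value"].to_numpy()
        denom = float(np.var(vals - mu - env_effects[i]))
        if denom == 0.0:
            raise ZeroDivisionError("zero within-environment phenotypic variance")
        ratios.append(var_g / denom)
    return float(np.mean(ratios))
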