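"""Genomic relationship matrix, Cholesky factors and network modality inputs.

The line x line genomic relationship matrix G (VanRaden method 1) summarises
marker-derived kinship.  Its triangular factor F provides compressed genomic
features: an observation on line j in environment i is described by three
blocks — an environment one-hot X_E, the line's factor row X_L = Z_L F, and an
interaction block X_EL = Z_EL (I ⊗ F) that places the same factor row in the
column block of environment i.  With the ``gram`` orientation (F F' = G) the
Gram matrices of the feature blocks reproduce the mixed-model covariances
Z_L G Z_L' and Z_EL (I ⊗ G) Z_EL', so a linear model on these features is
exactly a GBLUP.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .genotype_io import MarkerMatrix, RECODED

__all__ = [
    "RelationshipMatrix",
    "CholFactor",
    "ModalityInputs",
    "compute_grm",
    "chol_factor",
    "build_modality_inputs",
]

#: factor with F F' = G (lower triangular); feature Grams reproduce G
GRAM = "gram"
#: upper factor R with R' R = G, the literal textual convention
UPPER = "upper_GtLL"


@dataclasses.dataclass
class RelationshipMatrix:
    """Symmetric positive-definite genomic relationship matrix with line index."""

    G: np.ndarray
    line_ids: list[str]
    jitter: float = 0.0

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        J = len(self.line_ids)
        if self.G.shape != (J, J):
            raise ValueError(f"G shape {self.G.shape} does not match {J} lines")
        asym = np.max(np.abs(self.G - self.G.T)) if J else 0.0
        if asym > 1e-10:
            raise ValueError(f"G is asymmetric (max |G - G'| = {asym:.2e})")

    @property
    def n_lines(self) -> int:
        return self.G.shape[0]

    def line_index(self, line_id: str) -> int:
        try:
            return self.line_ids.index(line_id)
        except ValueError:
            raise KeyError(f"unknown line {line_id!r}") from None


@dataclasses.dataclass
class CholFactor:
    """Triangular square root of a relationship matrix.

    ``gram`` orientation: F is lower triangular with F F' = G.
    ``upper_GtLL`` orientation: F is upper triangular with F' F = G.
    """

    F: np.ndarray
    line_ids: list[str]
    orientation: str = GRAM

    def __post_init__(self) -> None:
        if self.orientation not in (GRAM, UPPER):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def reconstruct(self) -> np.ndarray:
        if self.orientation == GRAM:
            return self.F @ self.F.T
        return self.F.T @ self.F


@dataclasses.dataclass
class ModalityInputs:
    """Per-observation feature blocks for the multi-modal network.

    ``obs_index`` orders the (environment, line) pairs; environments are
    indexed lexicographically by identifier (recorded in ``env_ids``).
    """

    X_E: np.ndarray
    X_L: np.ndarray
    X_EL: np.ndarray
    obs_index: list[tuple[str, str]]
    env_ids: list[str]
    line_ids: list[str]

    @property
    def n_obs(self) -> int:
        return len(self.obs_index)

    def blocks(self, predictor: str = "E+G+GE") -> list[np.ndarray]:
        """Feature blocks for a predictor: 'G', 'E+G' or 'E+G+GE'."""
        if predictor == "G":
            return [self.X_L]
        if predictor == "E+G":
            return [self.X_E, self.X_L]
        if predictor == "E+G+GE":
            return [self.X_E, self.X_L, self.X_EL]
        raise ValueError(f"unknown predictor {predictor!r}")


def compute_grm(m: MarkerMatrix, jitter_scale: float = 1e-6) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix from a recoded, imputed matrix.

    Marker columns are centered by their means and G = W W' / c with
    c = sum_k 2 p_k (1 - p_k), p_k the +1-allele frequency on the {0, 1, 2}
    dosage scale.  A diagonal jitter of ``jitter_scale * mean(diag G)`` keeps
    the matrix factorable even with duplicated lines.
    """
    if m.coding_tag != RECODED:
        raise ValueError("compute_grm requires a recoded matrix")
    if np.isnan(m.values).any():
        raise ValueError("compute_grm requires an imputed (no-missing) matrix")
    if m.n_markers < 2:
        raise ValueError("at least two markers are required")
    dosage_mean = np.mean(m.values + 1.0, axis=0)
    p = dosage_mean / 2.0
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0.0:
        raise ValueError("all markers are monomorphic; G is undefined")
    W = m.values - np.mean(m.values, axis=0)
    G = (W @ W.T) / c
    G = 0.5 * (G + G.T)
    jitter = jitter_scale * float(np.mean(np.diag(G)))
    G[np.diag_indices_from(G)] += jitter
    return RelationshipMatrix(G, list(m.line_ids), jitter=jitter)


def chol_factor(G: RelationshipMatrix, orientation: str = GRAM) -> CholFactor:
    """Triangular factor of G in the requested orientation (deterministic).

    ``gram``: lower L with L L' = G.  ``upper_GtLL``: upper R with R'R = G.
    """
    try:
        if orientation == GRAM:
            F = scipy.linalg.cholesky(G.G, lower=True)
        elif orientation == UPPER:
            F = scipy.linalg.cholesky(G.G, lower=False)
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
    except scipy.linalg.LinAlgError:
        raise scipy.linalg.LinAlgError(
            "Cholesky factorization failed; increase the diagonal jitter on G"
        ) from None
    return CholFactor(F, list(G.line_ids), orientation=orientation)


def build_modality_inputs(
    obs: list[tuple[str, str]],
    F: CholFactor,
    env_ids: list[str] | None = None,
) -> ModalityInputs:
    """Assemble X_E, X_L and X_EL feature blocks for (environment, line) pairs.

    The interaction block realizes Z_EL (I ⊗ F) row by row — observation
    (i, j) is zero outside the environment-i column block, which holds the
    factor row of line j — so the (I·J) x (I·J) interaction relationship
    matrix is never materialized.
    """
    if env_ids is None:
        env_ids = sorted({env for env, _ in obs})
    env_pos = {env: i for i, env in enumerate(env_ids)}
    line_pos = {line: j for j, line in enumerate(F.line_ids)}
    n_env, n_lines = len(env_ids), len(F.line_ids)
    n_obs = len(obs)

    X_E = np.zeros((n_obs, n_env))
    X_L = np.zeros((n_obs, n_lines))
    X_EL = np.zeros((n_obs, n_env * n_lines))
    # X_L = Z_L F: observation on line j takes row j of the factor,
    # whichever orientation was requested
    rows = F.F
    for r, (env, line) in enumerate(obs):
        if env not in env_pos:
            raise KeyError(f"unknown environment {env!r}")
        if line not in line_pos:
            raise KeyError(f"unknown line {line!r}")
        i, j = env_pos[env], line_pos[line]
        X_E[r, i] = 1.0
        X_L[r, :] = rows[j]
        X_EL[r, i * n_lines : (i + 1) * n_lines] = rows[j]
    return ModalityInputs(
        X_E=X_E,
        X_L=X_L,
        X_EL=X_EL,
        obs_index=list(obs),
        env_ids=list(env_ids),
        line_ids=list(F.line_ids),
    )
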