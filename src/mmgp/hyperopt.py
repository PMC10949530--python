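"""Bayesian hyperparameter optimization over the network's search space.

A Gaussian-process surrogate (Matern-5/2 kernel) with expected-improvement
acquisition proposes hyperparameter vectors; integer dimensions are rounded
and clamped on decoding, log-scale dimensions (learning rate, weight decay)
are exponentiated.  The default search space mirrors the published domain:
per-modality depths and first-layer widths, fusion depth and width, L2
strength, dropout, log weight decay, patience and log learning rate.  The
budget counts total objective evaluations, including the initial quasi-random
points.  A pure random-search strategy with the same budget is available as a
cheap fallback.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .mmdl import ArchitectureSpec, TrainConfig

__all__ = [
    "Dimension",
    "SearchSpace",
    "TrialRecord",
    "default_search_space",
    "decode",
    "make_inner_split",
    "optimize",
]


@dataclasses.dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    integer: bool = False
    log: bool = False  # value used as exp(raw)

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: lower bound must be below upper bound")


@dataclasses.dataclass
class SearchSpace:
    dimensions: list[Dimension]

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dimensions]

    @property
    def bounds(self) -> np.ndarray:
        return np.array([[d.low, d.high] for d in self.dimensions])

    def validate(self, raw: np.ndarray) -> None:
        raw = np.asarray(raw, dtype=float)
        if raw.shape != (len(self.dimensions),):
            raise ValueError("raw point has wrong dimensionality")
        for v, d in zip(raw, self.dimensions):
            if not d.low <= v <= d.high:
                raise ValueError(f"{d.name}={v} outside bounds ({d.low}, {d.high})")


def default_search_space() -> SearchSpace:
    """Search domain for the three-modality network.

    Depths L1 in (1,4), L2/L3 in (1,6); fusion depth L in (0,4); first-layer
    widths N1 in (0,128), N2/N3 in (1,1024), fusion width N in (0,200); L2
    strength in (1e-8, 1e-2); dropout in (1e-4, 0.5); log weight decay in
    (ln 4e-5, ln 4e-1); patience in (0,128); log learning rate in
    (ln 1e-8, ln 1e-2).  Zero lower bounds on widths and patience are
    exclusive after decoding (clamped to >= 1); fusion depth 0 is meaningful
    (no fusion stack).
    """
    return SearchSpace(
        [
            Dimension("L1", 1, 4, integer=True),
            Dimension("L2", 1, 6, integer=True),
            Dimension("L3", 1, 6, integer=True),
            Dimension("L", 0, 4, integer=True),
            Dimension("N1", 0, 128, integer=True),
            Dimension("N2", 1, 1024, integer=True),
            Dimension("N3", 1, 1024, integer=True),
            Dimension("N", 0, 200, integer=True),
            Dimension("lambda_l2", 1e-8, 1e-2),
            Dimension("dropout", 1e-4, 0.5),
            Dimension("lwd", math.log(4e-5), math.log(4e-1), log=True),
            Dimension("Pat", 0, 128, integer=True),
            Dimension("llr", math.log(1e-8), math.log(1e-2), log=True),
        ]
    )


def decode_values(raw: np.ndarray, space: SearchSpace) -> dict[str, float | int]:
    """Round/clamp integer dimensions, exponentiate log dimensions."""
    space.validate(raw)
    out: dict[str, float | int] = {}
    for v, d in zip(raw, space.dimensions):
        if d.integer:
            iv = int(round(v))
            if d.name == "L":
                iv = max(0, iv)  # fusion depth 0 is a valid architecture
            else:
                iv = max(1, iv)
            out[d.name] = iv
        elif d.log:
            out[d.name] = float(math.exp(v))
        else:
            out[d.name] = float(v)
    return out


def decode(
    raw: np.ndarray,
    space: SearchSpace | None = None,
    *,
    seed: int = 0,
    epochs: int = 48,
) -> tuple[ArchitectureSpec, TrainConfig]:
    """Map a raw search-space point to architecture and training configs."""
    if space is None:
        space = default_search_space()
    vals = decode_values(raw, space)
    arch = ArchitectureSpec(
        modality_depths=[vals["L1"], vals["L2"], vals["L3"]],
        modality_first_widths=[vals["N1"], vals["N2"], vals["N3"]],
        fusion_depth=vals["L"],
        fusion_first_width=vals["N"] if vals["L"] > 0 else 0,
    )
    cfg = TrainConfig(
        lambda_l2=vals["lambda_l2"],
        dropout=vals["dropout"],
        lr0=vals["llr"],
        weight_decay_rate=vals["lwd"],
        patience=min(vals["Pat"], 10**9),
        epochs=epochs,
        seed=seed,
    )
    return arch, cfg


def make_inner_split(
    train_index: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Inner 10-fold split: folds 1-2 (20%) validate, folds 3-10 sub-train.

    Deterministic given the seed; the returned index arrays are disjoint and
    exhaust ``train_index``.
    """
    train_index = np.asarray(train_index)
    n = len(train_index)
    if n < 10:
        raise ValueError("inner split requires at least 10 training observations")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20851]))
    perm = rng.permutation(n)
    folds = np.array_split(perm, 10)
    val = np.sort(np.concatenate(folds[:2]))
    sub = np.sort(np.concatenate(folds[2:]))
    return train_index[sub], train_index[val]


@dataclasses.dataclass
class TrialRecord:
    raw: np.ndarray
    decoded: dict
    score: float
    seed: int

    @property
    def failed(self) -> bool:
        return not np.isfinite(self.score)


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


def optimize(
    objective,
    space: SearchSpace,
    n_iter: int = 50,
    n_init: int = 10,
    seed: int = 0,
    strategy: str = "gp",
    n_candidates: int = 512,
) -> tuple[TrialRecord, list[TrialRecord]]:
    """Minimize ``objective(raw_point)`` over the search space.

    ``n_iter`` is the total evaluation budget including the ``n_init``
    quasi-random (Sobol) initial points.  Strategy ``gp`` fits a Matern-5/2
    Gaussian process to the scored trials and proposes the
    expected-improvement maximizer over a seeded Sobol candidate set;
    ``random`` evaluates the budget uniformly at random.  Returns the
    incumbent (lowest finite score) and the full trial history.
    """
    if strategy not in ("gp", "random"):
        raise ValueError("strategy must be 'gp' or 'random'")
    if n_iter < 1:
        raise ValueError("budget must be >= 1")
    n_init = min(n_init, n_iter)
    rng = np.random.default_rng(seed)
    bounds = space.bounds
    lo, hi = bounds[:, 0], bounds[:, 1]
    ndim = len(space.dimensions)

    def evaluate(raw: np.ndarray) -> TrialRecord:
        decoded = decode_values(raw, space)
        try:
            score = float(objective(raw))
        except (FloatingPointError, RuntimeError):
            score = np.nan  # marked failed; the loop continues
        return TrialRecord(raw=raw, decoded=decoded, score=score, seed=seed)

    history: list[TrialRecord] = []
    if strategy == "random":
        for _ in range(n_iter):
            raw = rng.uniform(lo, hi)
            history.append(evaluate(raw))
    else:
        sobol = qmc.Sobol(ndim, scramble=True, seed=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # non-power-of-two draw
            init = lo + sobol.random(n_init) * (hi - lo)
        for raw in init:
            history.append(evaluate(raw))
        kernel = ConstantKernel(1.0, (1e-4, 1e4)) * Matern(
            length_scale=np.ones(ndim), length_scale_bounds=(1e-2, 1e2), nu=2.5
        ) + WhiteKernel(1e-6, (1e-12, 1e-1))
        for _ in range(n_iter - n_init):
            pts = np.array([t.raw for t in history if np.isfinite(t.score)])
            scores = np.array([t.score for t in history if np.isfinite(t.score)])
            if len(pts) < 2:
                history.append(evaluate(rng.uniform(lo, hi)))
                continue
            X = (pts - lo) / (hi - lo)
            mu_s, sd_s = scores.mean(), scores.std()
            ys = (scores - mu_s) / (sd_s if sd_s > 0 else 1.0)
            gp = GaussianProcessRegressor(
                kernel=kernel,
                normalize_y=False,
                n_restarts_optimizer=0,
                random_state=int(rng.integers(2**31)),
            )
            with warnings.catch_warnings():
                # surrogate hyperparameters need not converge tightly; the
                # acquisition only needs a reasonable mean/uncertainty field
                warnings.simplefilter("ignore")
                gp.fit(X, ys)
            cand = qmc.Sobol(
                ndim, scramble=True, seed=int(rng.integers(2**31))
            ).random(n_candidates)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # clipped near-zero variances
                mu_c, sigma_c = gp.predict(cand, return_std=True)
            ei = _expected_improvement(mu_c, sigma_c, float(ys.min()))
            raw = lo + cand[int(np.argmax(ei))] * (hi - lo)
            history.append(evaluate(raw))

    finite = [t for t in history if np.isfinite(t.score)]
    if not finite:
        err = RuntimeError("all optimization trials failed")
        err.history = history  # type: ignore[attr-defined]
        raise err
    best = min(finite, key=lambda t: t.score)
    return best, history
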