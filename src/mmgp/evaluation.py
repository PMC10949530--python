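"""Cross-validation protocols, prediction-accuracy metrics and model comparison.

Protocols: balanced k-fold over observations stratified by environment
(optionally with inverted training/testing roles for small-training-fraction
studies, and with repeats), and leave-one-environment-out (LOEO), where an
entire environment is predicted from the others.  Metrics: NRMSE (RMSE
normalized by the mean of the observed test values, with range and SD
alternatives) and Pearson's correlation.  Aggregation reports the mean and
standard deviation of each metric across folds or environments, and
``compare_models`` tallies strict win counts and relative-difference ranges
between two models' metric tables.

``load_reference_5fcv`` / ``load_reference_loeo`` return transcriptions of
the published wheat multi-environment-trial benchmark tables (five traits,
GBLUP vs the multi-modal network) used by the worked-example tests.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "FoldAssignment",
    "kfold_split",
    "loeo_split",
    "nrmse",
    "pearson_cor",
    "aggregate",
    "ComparisonSummary",
    "compare_models",
    "summarize_hyperparams",
    "load_reference_5fcv",
    "load_reference_loeo",
]


@dataclasses.dataclass
class FoldAssignment:
    """Per-observation fold labels for one split of the data.

    ``labels[i]`` is the fold (or, for LOEO, 1 for the held-out environment
    and 0 for training) of observation i.  ``iter_folds`` yields
    (train_indices, test_indices) pairs; with ``invert_roles`` a single fold
    trains and the remaining k-1 folds test.
    """

    scheme: str  # kfold | kfold_inverted | loeo
    k: int
    labels: np.ndarray
    seed: int | None = None
    held_out: str | None = None  # LOEO environment id

    def iter_folds(self):
        if self.scheme == "loeo":
            test = np.flatnonzero(self.labels == 1)
            train = np.flatnonzero(self.labels == 0)
            yield train, test
            return
        invert = self.scheme == "kfold_inverted"
        for fold in range(self.k):
            in_fold = np.flatnonzero(self.labels == fold)
            rest = np.flatnonzero(self.labels != fold)
            if invert:
                yield in_fold, rest
            else:
                yield rest, in_fold


def kfold_split(
    obs: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    invert_roles: bool = False,
    repeats: int = 1,
) -> list[FoldAssignment]:
    """Balanced k-fold partitions stratified by environment.

    Observations are shuffled within each environment and dealt round-robin,
    so global fold sizes differ by at most one while each fold samples every
    environment.  ``invert_roles=True`` trains on one fold and tests on the
    other k-1 (training fraction 1/k).  ``repeats`` re-randomizes with seeds
    derived from ``seed``; one FoldAssignment is returned per repeat.
    """
    n = len(obs)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} observations")
    env = obs["environment"].to_numpy()
    assignments = []
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 40927, rep]))
        order = []
        for e in sorted(pd.unique(env)):
            idx = np.flatnonzero(env == e)
            order.append(rng.permutation(idx))
        order = np.concatenate(order)
        labels = np.empty(n, dtype=int)
        # global round-robin over the stratified order keeps fold sizes
        # within one of each other
        labels[order] = np.arange(n) % k
        assignments.append(
            FoldAssignment(
                scheme="kfold_inverted" if invert_roles else "kfold",
                k=k,
                labels=labels,
                seed=seed,
            )
        )
    return assignments


def loeo_split(obs: pd.DataFrame, env_ids: list[str] | None = None) -> list[FoldAssignment]:
    """One assignment per environment: that environment tests, the rest train."""
    env = obs["environment"].to_numpy()
    present = list(pd.unique(env))
    if env_ids is None:
        env_ids = sorted(present)
    if len(present) < 2:
        raise ValueError("LOEO requires at least two environments")
    out = []
    for e in env_ids:
        mask = env == e
        if not mask.any():
            warnings.warn(f"environment {e!r} has no observations; excluded from LOEO")
            continue
        out.append(
            FoldAssignment(
                scheme="loeo", k=1, labels=mask.astype(int), held_out=str(e)
            )
        )
    return out


def nrmse(observed, predicted, normalizer: str = "mean") -> float:
    """Root-mean-squared error over a normalizer of the observed values.

    Normalizers: ``mean`` (default; scale-invariant for positive traits),
    ``range`` (max - min) or ``sd``.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    if normalizer == "mean":
        denom = float(np.mean(observed))
    elif normalizer == "range":
        denom = float(np.max(observed) - np.min(observed))
    elif normalizer == "sd":
        denom = float(np.std(observed, ddof=1))
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if denom == 0.0:
        raise ZeroDivisionError(
            f"{normalizer} of observed values is zero; choose another normalizer"
        )
    return rmse / denom


def pearson_cor(observed, predicted) -> float:
    """Sample Pearson correlation; constant inputs are an error, not 0."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 3:
        raise ValueError("observed and predicted must share a length >= 3")
    if np.std(observed) == 0.0 or np.std(predicted) == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(scipy.stats.pearsonr(observed, predicted).statistic)


def aggregate(records: pd.DataFrame, ndigits: int | None = 4) -> pd.DataFrame:
    """Mean and sample SD of nrmse/cor per (model, trait, predictor) group.

    ``records`` is a tidy table with columns model, trait, predictor, unit,
    nrmse, cor (one row per fold or environment).  Output rows are ordered
    lexicographically by (trait, model, predictor); single-record groups get
    SD 0.
    """
    grouped = records.groupby(["trait", "model", "predictor"], sort=True)
    rows = []
    for (trait, model, predictor), grp in grouped:
        rows.append(
            {
                "model": model,
                "trait": trait,
                "predictor": predictor,
                "nrmse": grp["nrmse"].mean(),
                "nrmse_sd": grp["nrmse"].std(ddof=1) if len(grp) > 1 else 0.0,
                "cor": grp["cor"].mean(),
                "cor_sd": grp["cor"].std(ddof=1) if len(grp) > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    if ndigits is not None:
        for c in ("nrmse", "nrmse_sd", "cor", "cor_sd"):
            out[c] = out[c].round(ndigits)
    return out


@dataclasses.dataclass
class ComparisonSummary:
    """Side-by-side metric table for two models with summary accessors.

    ``table`` holds one row per matched key with ``<metric>_a`` and
    ``<metric>_b`` columns.  Win counting is strict — ties favor neither
    model.  Relative differences are 100 * (x / y - 1), framed so the
    numerator is the model the caller designates as better.
    """

    table: pd.DataFrame
    keys: list[str]
    metrics: tuple[str, ...] = ("nrmse", "cor")
    model_a: str = "A"
    model_b: str = "B"

    def win_counts(self, metric: str, lower_is_better: bool | None = None) -> dict[str, int]:
        if lower_is_better is None:
            lower_is_better = metric == "nrmse"
        a = self.table[f"{metric}_a"]
        b = self.table[f"{metric}_b"]
        if lower_is_better:
            wins_a, wins_b = int((a < b).sum()), int((b < a).sum())
        else:
            wins_a, wins_b = int((a > b).sum()), int((b > a).sum())
        return {self.model_a: wins_a, self.model_b: wins_b, "n": len(self.table)}

    def grand_mean(self, metric: str) -> float:
        """Mean of the metric over both models' rows pooled."""
        return float(
            pd.concat([self.table[f"{metric}_a"], self.table[f"{metric}_b"]]).mean()
        )

    def relative_difference(
        self, metric: str, numerator: str, traits: list[str] | None = None
    ) -> pd.Series:
        """Per-key 100 * (numerator / denominator - 1), optionally trait-filtered."""
        tab = self.table
        if traits is not None:
            tab = tab[tab["trait"].isin(traits)]
        if numerator == self.model_a:
            num, den = tab[f"{metric}_a"], tab[f"{metric}_b"]
        elif numerator == self.model_b:
            num, den = tab[f"{metric}_b"], tab[f"{metric}_a"]
        else:
            raise ValueError(f"unknown model {numerator!r}")
        return (100.0 * (num / den - 1.0)).rename(f"rel_{metric}")


def compare_models(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metrics: tuple[str, ...] = ("nrmse", "cor"),
    model_a: str = "A",
    model_b: str = "B",
) -> ComparisonSummary:
    """Join two metric tables on their shared non-metric key columns.

    Keys are every column both tables share apart from the metrics and their
    SDs (typically trait, predictor and unit).  Unmatched keys are an error
    listing the difference.
    """
    drop = set(metrics) | {f"{m}_sd" for m in metrics} | {"model"}
    keys = [c for c in table_a.columns if c in table_b.columns and c not in drop]
    if not keys:
        raise ValueError("tables share no key columns")
    a = table_a.set_index(keys)
    b = table_b.set_index(keys)
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            f"unmatched keys — only in first table: {list(only_a)}; "
            f"only in second: {list(only_b)}"
        )
    merged = a[list(metrics)].add_suffix("_a").join(b[list(metrics)].add_suffix("_b"))
    merged = merged.reset_index()
    return ComparisonSummary(
        table=merged, keys=keys, metrics=metrics, model_a=model_a, model_b=model_b
    )


def summarize_hyperparams(
    trials: pd.DataFrame,
    group_cols: list[str],
    int_cols: list[str],
    real_cols: list[str],
) -> pd.DataFrame:
    """Per-group mode of integer hyperparameters (smallest value on ties) and
    arithmetic mean of real-valued ones."""

    def _mode_smallest(s: pd.Series):
        counts = s.value_counts()
        top = counts[counts == counts.max()]
        return min(top.index)

    rows = []
    for key, grp in trials.groupby(group_cols, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        row = dict(zip(group_cols, key))
        for c in int_cols:
            row[c] = _mode_smallest(grp[c])
        for c in real_cols:
            row[c] = float(grp[c].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _load_csv(name: str) -> pd.DataFrame:
    with importlib.resources.files("mmgp.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_reference_5fcv() -> pd.DataFrame:
    """Published five-fold cross-validation summary (mean and fold SD of NRMSE
    and Cor per model, trait and predictor) for the wheat benchmark."""
    return _load_csv("wheat_5fcv_reference.csv")


def load_reference_loeo() -> pd.DataFrame:
    """Published leave-one-environment-out metrics (NRMSE and Cor per model,
    trait, predictor and predicted environment) for the wheat benchmark."""
    return _load_csv("wheat_loeo_reference.csv")
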