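"""End-to-end experiment runner: split -> fit -> predict -> metric records.

Ties genotype QC, kinship features, the two regression models and the
cross-validation protocols together so a whole evaluation is one call.  Used
by the command-line interface and the example scripts; every stage seeds its
randomness from the run seed through named substreams.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import evaluation, gblup, kinship, mmdl
from .genotype_io import MarkerMatrix

__all__ = ["DLSettings", "default_dl_settings", "run_model_cv", "run_experiment"]

PREDICTORS = ("G", "E+G", "E+G+GE")
SCHEMES = ("5fcv", "loeo", "kfold_inverted")


@dataclasses.dataclass
class DLSettings:
    """Architecture and training settings for the network in a CV run.

    Widths are per modality in predictor order (X_E, X_L, X_EL); unused
    modalities are dropped for reduced predictors.
    """

    depths: tuple[int, int, int] = (1, 1, 1)
    first_widths: tuple[int, int, int] = (8, 64, 64)
    fusion_depth: int = 0
    fusion_width: int = 0
    train: mmdl.TrainConfig = dataclasses.field(default_factory=mmdl.TrainConfig)


def default_dl_settings(seed: int = 0) -> DLSettings:
    """Desk-scale defaults: one residual block per modality, direct output,
    mild L2, exponentially decaying Adam steps, the standard 32/48 protocol."""
    return DLSettings(
        train=mmdl.TrainConfig(
            lambda_l2=1e-6,
            dropout=0.0,
            lr0=3e-3,
            weight_decay_rate=0.02,
            patience=48,
            epochs=48,
            seed=seed,
        )
    )


def _modality_arch(settings: DLSettings, predictor: str) -> mmdl.ArchitectureSpec:
    take = {"G": [1], "E+G": [0, 1], "E+G+GE": [0, 1, 2]}[predictor]
    return mmdl.ArchitectureSpec(
        modality_depths=[settings.depths[i] for i in take],
        modality_first_widths=[settings.first_widths[i] for i in take],
        fusion_depth=settings.fusion_depth,
        fusion_first_width=settings.fusion_width,
    )


def _check_predictor_scheme(predictor: str, scheme: str) -> None:
    if predictor not in PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "loeo" and predictor == "E+G+GE":
        raise ValueError(
            "LOEO predicts an unseen environment; the interaction term (GE) "
            "cannot be used — choose predictor 'G' or 'E+G'"
        )


def _dl_blocks(
    inputs: kinship.ModalityInputs,
    rows: np.ndarray,
    predictor: str,
    train_env_mask: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Slice modality blocks for a row subset.

    For LOEO, ``train_env_mask`` marks the environment columns present in
    training; held-out-environment rows (whose own one-hot column the model
    never saw active) get a uniform weight over the training environments,
    the average-environment convention.
    """
    blocks = inputs.blocks(predictor)
    out = [b[rows].copy() for b in blocks]
    if predictor != "G" and train_env_mask is not None:
        X_E = out[0]
        unseen = X_E[:, train_env_mask].sum(axis=1) == 0
        if unseen.any():
            X_E[np.ix_(unseen, np.flatnonzero(train_env_mask))] = 1.0 / int(
                train_env_mask.sum()
            )
            X_E[np.ix_(unseen, np.flatnonzero(~train_env_mask))] = 0.0
    return out


def run_model_cv(
    pheno: pd.DataFrame,
    markers: MarkerMatrix,
    model: str,
    predictor: str = "E+G+GE",
    scheme: str = "5fcv",
    k: int = 5,
    seed: int = 0,
    repeats: int = 1,
    gblup_config: gblup.GBLUPConfig | None = None,
    dl_settings: DLSettings | None = None,
    normalizer: str = "mean",
    trait: str | None = None,
) -> pd.DataFrame:
    """Cross-validate one model; returns tidy metric records.

    ``pheno`` is a long table (environment, line, trait, value); ``markers``
    must be recoded and imputed.  One record per fold (or per held-out
    environment) with columns model, trait, predictor, unit, nrmse, cor.
    """
    _check_predictor_scheme(predictor, scheme)
    if model not in ("gblup", "dl"):
        raise ValueError(f"unknown model {model!r}")
    if trait is None:
        traits = pheno["trait"].unique()
        if len(traits) != 1:
            raise ValueError("multiple traits present; pass trait=")
        trait = str(traits[0])
    df = pheno[pheno["trait"] == trait].reset_index(drop=True)

    G = kinship.compute_grm(markers)
    if scheme == "loeo":
        assignments = evaluation.loeo_split(df)
    else:
        assignments = evaluation.kfold_split(
            df, k=k, seed=seed, invert_roles=(scheme == "kfold_inverted"),
            repeats=repeats,
        )

    env_ids = sorted(df["environment"].unique())
    if model == "dl":
        F = kinship.chol_factor(G, kinship.GRAM)
        obs = list(zip(df["environment"], df["line"]))
        inputs = kinship.build_modality_inputs(obs, F, env_ids=env_ids)

    records = []
    fold_counter = 0
    for assignment in assignments:
        for train_idx, test_idx in assignment.iter_folds():
            unit = (
                assignment.held_out
                if assignment.scheme == "loeo"
                else f"fold{fold_counter}"
            )
            y_train = df.iloc[train_idx]
            y_test = df.iloc[test_idx]
            if model == "gblup":
                cfg = gblup_config or gblup.GBLUPConfig(seed=seed + fold_counter)
                fit = gblup.fit_gblup(
                    y_train,
                    G,
                    cfg,
                    include_gE=(predictor == "E+G+GE"),
                    include_env=(predictor != "G"),
                )
                pred = gblup.predict(
                    fit, list(zip(y_test["environment"], y_test["line"]))
                )
            else:
                settings = dl_settings or default_dl_settings(seed=seed)
                arch = _modality_arch(settings, predictor)
                train_env_mask = None
                if assignment.scheme == "loeo" and predictor != "G":
                    train_envs = set(y_train["environment"])
                    train_env_mask = np.array(
                        [e in train_envs for e in inputs.env_ids]
                    )
                xb_train = _dl_blocks(inputs, train_idx, predictor, train_env_mask)
                xb_test = _dl_blocks(inputs, test_idx, predictor, train_env_mask)
                cfg = dataclasses.replace(settings.train, seed=settings.train.seed + fold_counter)
                net = mmdl.build_network(
                    arch, [b.shape[1] for b in xb_train], seed=cfg.seed
                )
                net, _ = mmdl.train(net, xb_train, y_train["value"].to_numpy(), cfg)
                pred = mmdl.predict(net, xb_test)
            obs_vals = y_test["value"].to_numpy()
            records.append(
                {
                    "model": "GBLUP" if model == "gblup" else "DL",
                    "trait": trait,
                    "predictor": predictor,
                    "unit": unit,
                    "nrmse": evaluation.nrmse(obs_vals, pred, normalizer=normalizer),
                    "cor": evaluation.pearson_cor(obs_vals, pred),
                }
            )
            fold_counter += 1
    return pd.DataFrame(records)


def run_experiment(
    pheno: pd.DataFrame,
    markers: MarkerMatrix,
    models: tuple[str, ...] = ("gblup", "dl"),
    **kwargs,
) -> pd.DataFrame:
    """Run several models under one protocol and stack their metric records."""
    frames = [run_model_cv(pheno, markers, model=m, **kwargs) for m in models]
    return pd.concat(frames, ignore_index=True)
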