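"""Covariate correction of the accessibility matrix.

Two related procedures:

* composition correction — per feature, OLS of accessibility on
  [1, age, cell fractions]; only the composition component (with fractions
  centered at *training* means) is subtracted, so the age effect survives.
  The coefficients can be estimated on a training fold and applied to both
  train and test, making the correction usable inside cross-validation
  without leaking test information.
* generic covariate removal — per feature, OLS on [1, (age), covariates],
  subtracting the centered covariate component. With ``preserve_age=False``
  the age column is omitted from the fit, so variance shared between age
  and the covariates is removed along with them.

Cell-composition designs use a non-redundant subset of the measured
populations by default (monocytes, B, NK, CD4 T, CD8 T), because the full
panel is collinear by construction (T = CD4 + CD8, lymphocytes = T + B +
NK, and the leaf fractions sum to ~1, leaving granulocytes as the implicit
reference level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ALL_POPULATIONS = (
    "monocytes", "granulocytes", "lymphocytes", "T", "CD4T", "CD8T", "B", "NK",
)
# non-redundant: the aggregates (T, lymphocytes) are sums of leaves, and the
# leaf fractions themselves sum to ~1, so one leaf (granulocytes) serves as
# the implicit reference level
DEFAULT_POPULATIONS = ("monocytes", "B", "NK", "CD4T", "CD8T")


@dataclass
class CompositionModelFit:
    """Per-feature OLS coefficients for [intercept, age, populations...]."""

    feature_ids: list
    populations: list
    intercept: np.ndarray
    beta_age: np.ndarray
    beta_comp: np.ndarray  # features x populations
    comp_train_means: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.beta_comp, index=self.feature_ids, columns=self.populations)
        df.insert(0, "beta_age", self.beta_age)
        df.insert(0, "intercept", self.intercept)
        return df


def _check_full_rank(design: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns whose removal restores full column rank
        collinear = []
        for j in range(design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def fit_composition_models(
    matrix: pd.DataFrame,
    ages,
    compositions: pd.DataFrame,
    populations=DEFAULT_POPULATIONS,
) -> CompositionModelFit:
    """Per-feature OLS of accessibility on [1, age, cell fractions]."""
    populations = [p for p in populations if p in compositions.columns]
    ages = np.asarray(ages, dtype=float)
    C = compositions[populations].to_numpy(dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite composition values")
    n, p = len(ages), len(populations)
    if n < p + 2:
        raise ValueError(f"need >= {p + 2} samples for {p} populations, got {n}")
    D = np.column_stack([np.ones(n), ages, C])
    _check_full_rank(D, ["intercept", "age", *populations])
    Y = matrix.to_numpy(dtype=float).T  # samples x features
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    return CompositionModelFit(
        feature_ids=list(matrix.index),
        populations=list(populations),
        intercept=beta[0],
        beta_age=beta[1],
        beta_comp=beta[2:].T,
        comp_train_means=C.mean(axis=0),
    )


def apply_composition_correction(
    fit: CompositionModelFit, matrix: pd.DataFrame, compositions: pd.DataFrame
) -> pd.DataFrame:
    """Subtract the composition component; the age term is left intact.

    corrected_ij = matrix_ij - sum_c beta_ci * (comp_cj - train_mean_c)
    """
    missing = [p for p in fit.populations if p not in compositions.columns]
    if missing:
        raise ValueError(f"composition table lacks populations {missing}")
    C = compositions[fit.populations].to_numpy(dtype=float)
    Cc = C - fit.comp_train_means
    adjust = fit.beta_comp @ Cc.T  # features x samples
    return pd.DataFrame(
        matrix.to_numpy(dtype=float) - adjust, index=matrix.index, columns=matrix.columns
    )


def remove_covariate_preserving_age(
    matrix: pd.DataFrame,
    covariate_design: pd.DataFrame,
    ages,
    preserve_age: bool = True,
) -> pd.DataFrame:
    """Remove covariate effects per feature, optionally shielding the age effect.

    Fits accessibility on [1, age (if preserve_age), covariates] and
    subtracts only the covariate component (covariates centered), in the
    manner of limma's removeBatchEffect with age in the retained design.
    """
    ages = np.asarray(ages, dtype=float)
    V = covariate_design.to_numpy(dtype=float)
    n = len(ages)
    cols = ["intercept"] + (["age"] if preserve_age else []) + list(covariate_design.columns)
    parts = [np.ones(n)] + ([ages] if preserve_age else []) + [V.T[i] for i in range(V.shape[1])]
    D = np.column_stack(parts)
    _check_full_rank(D, cols)
    Y = matrix.to_numpy(dtype=float).T
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    n_lead = 2 if preserve_age else 1
    beta_cov = beta[n_lead:]  # covariates x features
    Vc = V - V.mean(axis=0, keepdims=True)
    adjust = (Vc @ beta_cov).T  # features x samples
    return pd.DataFrame(
        matrix.to_numpy(dtype=float) - adjust, index=matrix.index, columns=matrix.columns
    )


def keep_only_composition_explained(
    matrix: pd.DataFrame, ages, compositions: pd.DataFrame,
    populations=DEFAULT_POPULATIONS,
) -> pd.DataFrame:
    """Strip everything the composition model cannot explain.

    The inverse experiment to composition correction: the residual of the
    [1, age, composition] fit is subtracted and the age component dropped,
    leaving intercept + composition-explained variation only. An age
    predictor trained on the result can only exploit composition signal.
    """
    fit = fit_composition_models(matrix, ages, compositions, populations)
    ages = np.asarray(ages, dtype=float)
    C = compositions[list(fit.populations)].to_numpy(dtype=float)
    fitted_comp = fit.intercept[:, None] + fit.beta_comp @ C.T
    return pd.DataFrame(fitted_comp, index=matrix.index, columns=matrix.columns)


def composition_fold_preprocess(
    compositions: pd.DataFrame, ages, populations=DEFAULT_POPULATIONS
):
    """Build a nested-CV hook applying train-estimated composition correction.

    Returns ``f(Xa, train_mask, test_mask) -> corrected Xa`` for
    :func:`atacage.clock.nested_cv`; X is samples x features there, so the
    hook transposes around the per-feature fit. Coefficients come from the
    training fold only.
    """
    comp = compositions.copy()
    ages = np.asarray(ages, dtype=float)

    def hook(Xa: np.ndarray, tr: np.ndarray, te: np.ndarray) -> np.ndarray:
        mat = pd.DataFrame(Xa.T)  # features x samples
        fit = fit_composition_models(
            mat.loc[:, tr], ages[tr], comp.loc[tr], populations
        )
        corrected = apply_composition_correction(fit, mat, comp)
        return corrected.to_numpy().T

    return hook


def cv_corrected_clock(
    matrix: pd.DataFrame,
    ages: pd.Series,
    compositions: pd.DataFrame,
    folds: pd.Series,
    lambda_grid=None,
    alpha_grid=None,
    populations=DEFAULT_POPULATIONS,
) -> dict:
    """Nested CV with within-fold train-estimated composition correction.

    Inside each outer fold the composition model is fitted on training
    samples only and used to correct both train and test before the usual
    inner/outer elastic-net procedure.
    """
    from . import clock as clk

    comp = compositions.reset_index(drop=True)
    hook = composition_fold_preprocess(comp, np.asarray(ages, dtype=float), populations)
    kwargs = {}
    if lambda_grid is not None:
        kwargs["lambda_grid"] = lambda_grid
    if alpha_grid is not None:
        kwargs["alpha_grid"] = alpha_grid
    X = matrix.T  # samples x features
    return clk.nested_cv(X, pd.Series(np.asarray(ages, dtype=float), index=X.index),
                         pd.Series(np.asarray(folds), index=X.index),
                         fold_preprocess=hook, **kwargs)
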