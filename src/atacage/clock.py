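"""Elastic-net age prediction with nested leave-one-group-out CV.

The clock is a penalized linear model on standardized features minimizing

    (1/2n) * ||y - Xb||^2 + lambda * (alpha_l1 * ||b||_1 + (1-alpha_l1)/2 * ||b||_2^2)

with an unpenalized intercept. Samples are dealt into k age-balanced groups
(sort by age, deal consecutive blocks round-robin) so every group spans the
cohort's age range; the outer CV loop holds out one group at a time while
the inner loop (over the remaining groups) picks (lambda, alpha_l1) by mean
RMSE. Reported metrics: RMSE, MEDIAN absolute error, and Pearson r.

Fitting delegates to scikit-learn's coordinate descent; the pure-ridge case
(alpha_l1 = 0) uses the exact closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 2, 20))
DEFAULT_ALPHA_GRID = (0.1, 0.5, 0.9)
N_GROUPS_DEFAULT = 11


# ---------------------------------------------------------------------------
# Group assignment

def assign_groups(ages, k: int = N_GROUPS_DEFAULT, seed: int = 0) -> pd.Series:
    """Deal samples into k groups whose age compositions span the age range.

    Samples are sorted by age; consecutive blocks of k samples are dealt
    round-robin to groups 1..k, with within-block order shuffled by
    ``seed`` so ties and group order are randomized but reproducible. The
    trailing partial block is dealt to a random subset of distinct groups.
    """
    ages = pd.Series(ages)
    n = len(ages)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    order = np.argsort(ages.to_numpy(), kind="mergesort")
    groups = np.empty(n, dtype=int)
    for lo in range(0, n, k):
        block = order[lo : lo + k]
        targets = rng.permutation(k)[: len(block)] + 1
        groups[block] = targets
    return pd.Series(groups, index=ages.index, name="group")


# ---------------------------------------------------------------------------
# Model

@dataclass
class ClockModel:
    """Standardizer + elastic-net coefficients for age prediction."""

    feature_ids: list
    means: np.ndarray
    sds: np.ndarray
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    alpha_l1: float
    meta: dict = field(default_factory=dict)

    @property
    def selected_features(self) -> list:
        return [f for f, c in zip(self.feature_ids, self.coefficients) if c != 0]

    def to_json(self, path=None) -> str:
        payload = {
            "feature_ids": list(map(str, self.feature_ids)),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "lambda": float(self.lambda_),
            "alpha_l1": float(self.alpha_l1),
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ClockModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_ids=d["feature_ids"],
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            coefficients=np.asarray(d["coefficients"]),
            intercept=d["intercept"],
            lambda_=d["lambda"],
            alpha_l1=d["alpha_l1"],
            meta=d.get("meta", {}),
        )


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Training means/sds; zero-variance features flagged (sd set to 1, masked)."""
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    live = sds > 0
    sds_safe = np.where(live, sds, 1.0)
    return means, sds_safe, live


def fit_elastic_net(
    X: pd.DataFrame | np.ndarray,
    y,
    lambda_: float,
    alpha_l1: float,
    max_iter: int = 20_000,
    tol: float = 1e-7,
) -> ClockModel:
    """Fit the standardized elastic net; zero-variance features get coef 0."""
    feature_ids = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.shape(X)[1]))
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    means, sds, live = _standardize_fit(Xa)
    Z = (Xa - means) / sds
    Zl = Z[:, live]
    coefs = np.zeros(Xa.shape[1])
    if alpha_l1 == 0.0:
        # exact ridge closed form: (Z'Z + n*lambda*I)^-1 Z'(y - ybar)
        n = len(ya)
        yc = ya - ya.mean()
        A = Zl.T @ Zl + n * lambda_ * np.eye(Zl.shape[1])
        coefs[live] = np.linalg.solve(A, Zl.T @ yc)
        intercept = float(ya.mean())
    else:
        from sklearn.linear_model import ElasticNet

        en = ElasticNet(
            alpha=lambda_, l1_ratio=alpha_l1, fit_intercept=True,
            max_iter=max_iter, tol=tol,
        )
        en.fit(Zl, ya)
        coefs[live] = en.coef_
        intercept = float(en.intercept_)
    return ClockModel(
        feature_ids=feature_ids,
        means=means,
        sds=sds,
        coefficients=coefs,
        intercept=intercept,
        lambda_=lambda_,
        alpha_l1=alpha_l1,
    )


def predict(model: ClockModel, X_new: pd.DataFrame) -> pd.Series:
    """Apply the stored standardizer and coefficients to new samples."""
    missing = [f for f in model.feature_ids if f not in X_new.columns]
    if missing:
        raise ValueError(f"missing features in new data: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    Z = (X_new[model.feature_ids].to_numpy(dtype=float) - model.means) / model.sds
    return pd.Series(Z @ model.coefficients + model.intercept, index=X_new.index, name="predicted_age")


def kkt_violation(model: ClockModel, X: pd.DataFrame | np.ndarray, y) -> float:
    """Max violation of the elastic-net stationarity conditions on (X, y).

    For zero coefficients: |(1/n) Z_j' r| <= lambda*alpha_l1; for active
    ones the subgradient equality must hold. Returns the largest excess.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    Z = (Xa - model.means) / model.sds
    n = len(ya)
    r = ya - (Z @ model.coefficients + model.intercept)
    g = Z.T @ r / n - model.lambda_ * (1 - model.alpha_l1) * model.coefficients
    lam1 = model.lambda_ * model.alpha_l1
    active = model.coefficients != 0
    v_zero = np.max(np.abs(g[~active]) - lam1, initial=0.0)
    v_active = np.max(np.abs(g[active] - lam1 * np.sign(model.coefficients[active])), initial=0.0)
    return float(max(v_zero, v_active, 0.0))


# ---------------------------------------------------------------------------
# Metrics

def metrics(predicted, true) -> dict:
    """RMSE, MEDIAN absolute error, Pearson r (NaN when undefined)."""
    yp = np.asarray(predicted, dtype=float)
    yt = np.asarray(true, dtype=float)
    if len(yp) != len(yt) or len(yp) < 2:
        raise ValueError("predicted/true must have equal length >= 2")
    resid = yp - yt
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae_median = float(np.median(np.abs(resid)))
    if np.std(yp) == 0 or np.std(yt) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(yp, yt)[0])
    return {"rmse": rmse, "mae_median": mae_median, "pearson_r": r}


# ---------------------------------------------------------------------------
# Nested cross-validation

def _inner_select(
    Xtr: np.ndarray, ytr: np.ndarray, inner_groups: np.ndarray,
    lambda_grid, alpha_grid,
) -> tuple[float, float]:
    """Leave-one-group-out selection of (lambda, alpha_l1) by mean RMSE.

    Uses scikit-learn's path solver (warm-started over the lambda grid) per
    l1 ratio; standardization is refit inside every inner training split.
    """
    from sklearn.linear_model import ElasticNet

    lambdas = sorted(lambda_grid, reverse=True)
    uniq = np.unique(inner_groups)
    sse = {(l, a): 0.0 for l in lambdas for a in alpha_grid}
    for g in uniq:
        tr = inner_groups != g
        te = ~tr
        means, sds, live = _standardize_fit(Xtr[tr])
        Ztr = ((Xtr[tr] - means) / sds)[:, live]
        Zte = ((Xtr[te] - means) / sds)[:, live]
        for a in alpha_grid:
            en = ElasticNet(alpha=lambdas[0], l1_ratio=a, warm_start=True,
                            max_iter=3_000, tol=1e-3)
            for lam in lambdas:
                en.set_params(alpha=lam)
                en.fit(Ztr, ytr[tr])
                pred = Zte @ en.coef_ + en.intercept_
                sse[(lam, a)] += float(np.sum((pred - ytr[te]) ** 2))
    best = min(sse, key=lambda key: (sse[key], -key[0], key[1]))
    return best


def nested_cv(
    X: pd.DataFrame,
    y: pd.Series,
    folds: pd.Series,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
    fold_preprocess=None,
) -> dict:
    """Nested leave-one-group-out CV report.

    For each outer group: hyperparameters are selected by LOGO CV over the
    remaining groups, a model is refit on all non-held-out samples, and the
    held-out group is predicted once. ``fold_preprocess(X, train_mask,
    test_mask) -> X_transformed`` optionally transforms features per fold
    using training-fold information only (e.g. composition correction).

    Returns dict with per-sample predictions, per-fold metrics, aggregate
    mean +/- sd, and per-fold selected-feature counts.
    """
    if len(lambda_grid) == 0 or len(alpha_grid) == 0:
        raise ValueError("hyperparameter grids must be non-empty")
    y = pd.Series(y)
    folds = pd.Series(folds).reindex(y.index)
    Xa = X.to_numpy(dtype=float)
    ya = y.to_numpy(dtype=float)
    ga = folds.to_numpy()
    preds = pd.Series(np.nan, index=y.index, name="predicted_age")
    fold_rows = []
    for g in np.unique(ga):
        te = ga == g
        tr = ~te
        if te.sum() < 1:
            raise ValueError(f"group {g} is empty")
        Xf = Xa
        if fold_preprocess is not None:
            Xf = fold_preprocess(Xa, tr, te)
        lam, a = _inner_select(Xf[tr], ya[tr], ga[tr], lambda_grid, alpha_grid)
        model = fit_elastic_net(
            pd.DataFrame(Xf[tr], columns=X.columns), ya[tr], lam, a,
            max_iter=5_000, tol=1e-5,
        )
        yhat = predict(model, pd.DataFrame(Xf[te], columns=X.columns)).to_numpy()
        preds.iloc[np.flatnonzero(te)] = yhat
        m = metrics(yhat, ya[te]) if te.sum() >= 2 else {"rmse": np.nan, "mae_median": np.nan, "pearson_r": np.nan}
        fold_rows.append(
            {"group": g, "n_test": int(te.sum()), "lambda": lam, "alpha_l1": a,
             "n_selected": int(np.sum(model.coefficients != 0)), **m}
        )
    fold_df = pd.DataFrame(fold_rows)
    agg = {
        k: {"mean": float(fold_df[k].mean()), "sd": float(fold_df[k].std(ddof=1))}
        for k in ("rmse", "mae_median", "pearson_r", "n_selected")
    }
    overall = metrics(preds.to_numpy(), ya)
    return {
        "predictions": preds,
        "fold_metrics": fold_df,
        "aggregate": agg,
        "overall": overall,
    }


def train_final(
    X: pd.DataFrame,
    y: pd.Series,
    folds: pd.Series,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
) -> ClockModel:
    """Hyperparameters by (non-nested) LOGO CV on all samples; fit on all."""
    ya = np.asarray(y, dtype=float)
    lam, a = _inner_select(
        X.to_numpy(dtype=float), ya, pd.Series(folds).to_numpy(), lambda_grid, alpha_grid
    )
    model = fit_elastic_net(X, ya, lam, a)
    model.meta["n_samples"] = int(len(ya))
    return model


def concat_multiomic(
    atac_matrix: pd.DataFrame, rna_matrix: pd.DataFrame, common_samples=None
) -> pd.DataFrame:
    """Stack OCR and gene features with atac:/rna: prefixed ids.

    Returned orientation is feature x sample (like the inputs); downstream
    standardization puts both blocks on the same scale.
    """
    if common_samples is None:
        common_samples = [s for s in atac_matrix.columns if s in set(rna_matrix.columns)]
    common_samples = list(common_samples)
    if not common_samples:
        raise ValueError("no common samples")
    a = atac_matrix[common_samples].copy()
    a.index = ["atac:" + str(i) for i in a.index]
    r = rna_matrix[common_samples].copy()
    r.index = ["rna:" + str(i) for i in r.index]
    joined = pd.concat([a, r])
    if joined.index.duplicated().any():
        raise ValueError("feature id collision after modality prefixing")
    return joined
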