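"""NIPALS PLS1 regression with cross-validated model selection.

Partial least squares projects the autoscaled descriptor block X onto a
small number of orthogonal latent vectors (LVs) chosen to covary maximally
with the response, then regresses on the LV scores.  This handles the
strong collinearity typical of molecular-descriptor blocks.  The
implementation is classical NIPALS PLS1 with X-deflation:

    w_a = X'y / ||X'y||,  t_a = X w_a,  p_a = X't_a / t_a't_a,
    q_a = y't_a / t_a't_a,  X <- X - t_a p_a',  y <- y - q_a t_a

and regression vector B = W (P'W)^{-1} q on the autoscaled variables.  At
full rank (as many LVs as descriptors) PLS coincides with ordinary least
squares, which the test suite uses as an oracle.

Model assessment follows standard QSPR practice: R^2 and RMSEc on the
training fit, leave-one-out Q^2cv / RMSEcv with autoscaling recomputed
inside every fold, and external Q^2ext (Q^2_F1 convention, denominator
about the training mean) with RMSEp on a held-out validation set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .selection import autoscale


def _as_matrix(X, descriptor_names: Sequence[str] | None):
    if isinstance(X, pd.DataFrame):
        if descriptor_names is not None:
            missing = [c for c in descriptor_names if c not in X.columns]
            if missing:
                raise KeyError(f"missing descriptor column(s): {missing}")
            X = X[list(descriptor_names)]
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    names = list(descriptor_names) if descriptor_names is not None else [
        f"x{j}" for j in range(arr.shape[1])
    ]
    return arr, names


@dataclass
class PLSModel:
    """Fitted PLS1 model with scaling, loadings, scores and diagnostics.

    ``coef_scaled`` acts on autoscaled descriptors; ``coef_original`` and
    ``intercept`` reproduce predictions directly on the original scale.
    Explained-variance entries are percentages per latent vector.
    """

    n_lv: int
    selected_descriptors: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    x_weights: np.ndarray      # (p, A)
    x_loadings: np.ndarray     # (p, A)
    y_loadings: np.ndarray     # (A,)
    scores: np.ndarray         # (n, A) training scores
    coef_scaled: np.ndarray    # (p,)
    coef_original: np.ndarray  # (p,)
    intercept: float
    explained_x_variance: list[float] = field(default_factory=list)
    explained_y_variance: list[float] = field(default_factory=list)

    def to_json(self, path, extra: dict | None = None) -> None:
        payload = {
            "n_lv": self.n_lv,
            "selected_descriptors": self.selected_descriptors,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef_scaled": self.coef_scaled.tolist(),
            "coef_original": self.coef_original.tolist(),
            "intercept": self.intercept,
            "explained_x_variance": self.explained_x_variance,
            "explained_y_variance": self.explained_y_variance,
        }
        if extra:
            payload.update(extra)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PLSModel":
        """Rebuild a model from its JSON serialization.

        Training scores are not serialized; the restored model predicts and
        projects but carries an empty score block.
        """
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        n_lv = int(d["n_lv"])
        return cls(
            n_lv=n_lv,
            selected_descriptors=list(d["selected_descriptors"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            y_mean=float(d["y_mean"]),
            y_sd=float(d["y_sd"]),
            x_weights=np.asarray(d["x_weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            scores=np.zeros((0, n_lv)),
            coef_scaled=np.asarray(d["coef_scaled"], dtype=float),
            coef_original=np.asarray(d["coef_original"], dtype=float),
            intercept=float(d["intercept"]),
            explained_x_variance=list(d["explained_x_variance"]),
            explained_y_variance=list(d["explained_y_variance"]),
        )


def _nipals(Xs: np.ndarray, ys: np.ndarray, n_lv: int):
    """Run NIPALS PLS1 on autoscaled data; returns (W, P, q, T)."""
    n, p = Xs.shape
    X = Xs.copy()
    y = ys.copy()
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    T = np.empty((n, n_lv))
    for a in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise np.linalg.LinAlgError(
                f"X'y vanished at component {a + 1}: n_lv={n_lv} exceeds the "
                "predictive rank of X"
            )
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            raise np.linalg.LinAlgError(
                f"degenerate score vector at component {a + 1}; reduce n_lv"
            )
        pa = (X.T @ t) / tt
        qa = float(y @ t) / tt
        X -= np.outer(t, pa)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
    return W, P, q, T


def fit_pls(
    X,
    y,
    n_lv: int,
    descriptor_names: Sequence[str] | None = None,
) -> PLSModel:
    """Fit a PLS1 model on raw (unscaled) X, y; autoscaling is internal.

    ``n_lv`` must not exceed the rank of the scaled descriptor block; the
    NIPALS recursion raises if the response is exhausted earlier.
    """
    Xr, names = _as_matrix(X, descriptor_names)
    yr = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(Xr)) or not np.all(np.isfinite(yr)):
        raise ValueError("non-finite values in X or y")
    if Xr.shape[0] != yr.shape[0]:
        raise ValueError("X and y row counts differ")
    if not 1 <= n_lv <= Xr.shape[1]:
        raise ValueError(f"n_lv must be in [1, {Xr.shape[1]}]")
    if n_lv > min(Xr.shape[0] - 1, int(np.linalg.matrix_rank(Xr - Xr.mean(axis=0)))):
        raise ValueError(f"n_lv={n_lv} exceeds the rank of the centered X block")
    Xs, xm, xs = autoscale(Xr)
    ym = float(yr.mean())
    ysd = float(yr.std(ddof=1))
    if ysd == 0.0:
        raise ValueError("response y has zero variance")
    ys = (yr - ym) / ysd

    W, P, q, T = _nipals(Xs, ys, n_lv)
    coef_scaled = W @ np.linalg.solve(P.T @ W, q)
    coef_original = ysd * coef_scaled / xs
    intercept = ym - float(coef_original @ xm)

    ssx = float(np.sum(Xs**2))
    ssy = float(np.sum(ys**2))
    tt = np.einsum("ia,ia->a", T, T)
    x_pct = (tt * np.einsum("ja,ja->a", P, P)) / ssx * 100.0
    y_pct = (q**2 * tt) / ssy * 100.0

    return PLSModel(
        n_lv=n_lv,
        selected_descriptors=names,
        x_mean=xm,
        x_sd=xs,
        y_mean=ym,
        y_sd=ysd,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef_scaled=coef_scaled,
        coef_original=coef_original,
        intercept=intercept,
        explained_x_variance=[float(v) for v in x_pct],
        explained_y_variance=[float(v) for v in y_pct],
    )


def predict(model: PLSModel, X_new) -> np.ndarray:
    """Predict responses on the original scale (kcal/mol for E_ads models)."""
    Xr, _ = _as_matrix(X_new, model.selected_descriptors)
    if Xr.shape[1] != len(model.selected_descriptors):
        raise ValueError("descriptor count mismatch")
    Xs = (Xr - model.x_mean) / model.x_sd
    return model.y_mean + model.y_sd * (Xs @ model.coef_scaled)


def project_scores(model: PLSModel, X_new) -> np.ndarray:
    """Latent-vector scores of new samples by projection (no refit)."""
    Xr, _ = _as_matrix(X_new, model.selected_descriptors)
    Xs = (Xr - model.x_mean) / model.x_sd
    R = model.x_weights @ np.linalg.inv(model.x_loadings.T @ model.x_weights)
    return Xs @ R


def fitted_statistics(model: PLSModel, X, y) -> tuple[float, float]:
    """(R^2, RMSEc) of the model on the given data."""
    yr = np.asarray(y, dtype=float).ravel()
    resid = yr - predict(model, X)
    tss = float(np.sum((yr - yr.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss
    rmse = float(np.sqrt(np.mean(resid**2)))
    return r2, rmse


def _loo_press_per_lv(Xr: np.ndarray, yr: np.ndarray, max_lv: int) -> np.ndarray:
    """Squared leave-one-out prediction errors, shape (n, max_lv).

    All n folds run simultaneously as a batched NIPALS (autoscaling
    recomputed inside every fold); entry [f, a-1] is the squared error of
    the a-LV model predicting the held-out sample f.
    """
    n, p = Xr.shape
    idx = np.arange(n)
    keep = np.stack([np.delete(idx, f) for f in range(n)])  # (n, n-1)
    X3 = Xr[keep]                                           # (n, n-1, p)
    y3 = yr[keep]                                           # (n, n-1)
    xm = X3.mean(axis=1)
    xsd = X3.std(axis=1, ddof=1)
    if np.any(xsd == 0.0):
        raise ValueError("a leave-one-out fold has a zero-variance descriptor column")
    ym = y3.mean(axis=1)
    ysd = y3.std(axis=1, ddof=1)
    X3 = (X3 - xm[:, None, :]) / xsd[:, None, :]
    y3 = (y3 - ym[:, None]) / ysd[:, None]
    xq = (Xr - xm) / xsd                                    # held-out rows, scaled
    W = np.zeros((n, p, max_lv))
    P = np.zeros((n, p, max_lv))
    Q = np.zeros((n, max_lv))
    eps = 1e-300
    for a in range(max_lv):
        w = np.einsum("fij,fi->fj", X3, y3)
        w /= np.linalg.norm(w, axis=1, keepdims=True) + eps
        t = np.einsum("fij,fj->fi", X3, w)
        tt = np.einsum("fi,fi->f", t, t) + eps
        pa = np.einsum("fij,fi->fj", X3, t) / tt[:, None]
        qa = np.einsum("fi,fi->f", y3, t) / tt
        X3 -= t[:, :, None] * pa[:, None, :]
        y3 -= qa[:, None] * t
        W[:, :, a], P[:, :, a], Q[:, a] = w, pa, qa
    press = np.empty((n, max_lv))
    for a in range(1, max_lv + 1):
        PtW = np.einsum("fja,fjb->fab", P[:, :, :a], W[:, :, :a])
        sol = np.linalg.solve(PtW, Q[:, :a, None])[..., 0]
        B = np.einsum("fja,fa->fj", W[:, :, :a], sol)
        yhat = ym + ysd * np.einsum("fj,fj->f", xq, B)
        press[:, a - 1] = (yr - yhat) ** 2
    return press


def loo_cv(X, y, n_lv: int, descriptor_names: Sequence[str] | None = None):
    """Leave-one-out cross-validation: returns (Q^2cv, RMSEcv).

    Each of the n folds refits the model (with autoscaling recomputed on
    the n-1 retained samples) and predicts the held-out sample; Q^2cv is
    1 - PRESS/TSS about the full-training mean, RMSEcv = sqrt(PRESS/n).
    """
    Xr, _ = _as_matrix(X, descriptor_names)
    yr = np.asarray(y, dtype=float).ravel()
    if Xr.shape[0] < 3:
        raise ValueError("leave-one-out cross-validation needs n >= 3")
    if not 1 <= n_lv <= Xr.shape[1]:
        raise ValueError(f"n_lv must be in [1, {Xr.shape[1]}]")
    sq = _loo_press_per_lv(Xr, yr, n_lv)[:, n_lv - 1]
    press = float(sq.sum())
    tss = float(np.sum((yr - yr.mean()) ** 2))
    return 1.0 - press / tss, float(np.sqrt(press / len(yr)))


def rmse_cv_per_lv(X, y, max_lv: int, descriptor_names: Sequence[str] | None = None):
    """RMSEcv for every LV count 1..max_lv in one batched LOO pass."""
    Xr, _ = _as_matrix(X, descriptor_names)
    yr = np.asarray(y, dtype=float).ravel()
    max_lv = min(max_lv, Xr.shape[1], Xr.shape[0] - 2)
    sq = _loo_press_per_lv(Xr, yr, max_lv)
    return np.sqrt(sq.mean(axis=0))


def select_n_lvs(X, y, max_lv: int, descriptor_names: Sequence[str] | None = None) -> int:
    """Latent-vector count minimizing RMSEcv; ties go to fewer LVs."""
    rmse = rmse_cv_per_lv(X, y, max_lv, descriptor_names)
    return int(np.argmin(rmse)) + 1  # argmin returns the first (smallest) min


def external_validation(model: PLSModel, X_val, y_val) -> tuple[float, float]:
    """(Q^2ext, RMSEp) on an independent validation set.

    Q^2ext follows the Q^2_F1 convention: 1 - sum (y - yhat)^2 /
    sum (y - mean(y_train))^2, with the training mean taken from the model.
    """
    yv = np.asarray(y_val, dtype=float).ravel()
    if yv.size == 0:
        raise ValueError("validation set is empty")
    yhat = predict(model, X_val)
    press = float(np.sum((yv - yhat) ** 2))
    denom = float(np.sum((yv - model.y_mean) ** 2))
    return 1.0 - press / denom, float(np.sqrt(press / yv.size))


def explained_variance(model: PLSModel, X, y) -> tuple[np.ndarray, np.ndarray]:
    """Per-LV explained variance (%) of the autoscaled X and y blocks.

    Computed from rank-one reconstructions t_a p_a' (resp. q_a t_a) of the
    given data projected through the model; on the training data this
    reproduces the percentages stored at fit time.
    """
    Xr, _ = _as_matrix(X, model.selected_descriptors)
    yr = np.asarray(y, dtype=float).ravel()
    Xs = (Xr - model.x_mean) / model.x_sd
    ys = (yr - model.y_mean) / model.y_sd
    T = project_scores(model, X)
    ssx = float(np.sum(Xs**2))
    ssy = float(np.sum(ys**2))
    tt = np.einsum("ia,ia->a", T, T)
    x_pct = tt * np.einsum("ja,ja->a", model.x_loadings, model.x_loadings) / ssx * 100.0
    y_pct = model.y_loadings**2 * tt / ssy * 100.0
    return x_pct, y_pct


@dataclass
class ValidationReport:
    """Fit, cross-validation and external-validation statistics."""

    r2: float
    q2_cv: float
    q2_ext: float
    rmse_c: float
    rmse_cv: float
    rmse_p: float

    def __post_init__(self) -> None:
        if self.q2_cv > self.r2 + 1e-12:
            warnings.warn(
                f"Q2cv ({self.q2_cv:.4f}) exceeds R2 ({self.r2:.4f}); "
                "check the fit",
                stacklevel=2,
            )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1)

    def to_text(self) -> str:
        return (
            f"R2      = {self.r2:.4f}   RMSEc  = {self.rmse_c:.4f} kcal/mol\n"
            f"Q2cv    = {self.q2_cv:.4f}   RMSEcv = {self.rmse_cv:.4f} kcal/mol\n"
            f"Q2ext   = {self.q2_ext:.4f}   RMSEp  = {self.rmse_p:.4f} kcal/mol\n"
        )


def validate_model(model: PLSModel, X_train, y_train, X_val, y_val) -> ValidationReport:
    """Assemble the full OECD-style validation report for a fitted model."""
    r2, rmse_c = fitted_statistics(model, X_train, y_train)
    q2_cv, rmse_cv = loo_cv(
        X_train, y_train, model.n_lv, descriptor_names=model.selected_descriptors
    )
    q2_ext, rmse_p = external_validation(model, X_val, y_val)
    return ValidationReport(r2, q2_cv, q2_ext, rmse_c, rmse_cv, rmse_p)


def export_interpretation(
    model: PLSModel,
    X_train,
    X_val=None,
    train_labels: Sequence[int] | None = None,
    val_labels: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loadings and score tables for mechanistic interpretation.

    Loadings: one row per selected descriptor, one column per LV.  Scores:
    training congeners carry their fitted scores; validation congeners are
    projected through the model, never refit.
    """
    lv_cols = [f"LV{a + 1}" for a in range(model.n_lv)]
    loadings = pd.DataFrame(
        model.x_loadings, index=model.selected_descriptors, columns=lv_cols
    )
    loadings.index.name = "descriptor"
    frames = []
    t_train = pd.DataFrame(model.scores, columns=lv_cols)
    t_train["set_label"] = "training"
    if train_labels is not None:
        t_train.insert(0, "index", list(train_labels))
    frames.append(t_train)
    if X_val is not None:
        t_val = pd.DataFrame(project_scores(model, X_val), columns=lv_cols)
        t_val["set_label"] = "validation"
        if val_labels is not None:
            t_val.insert(0, "index", list(val_labels))
        frames.append(t_val)
    scores = pd.concat(frames, ignore_index=True)
    return loadings, scores
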