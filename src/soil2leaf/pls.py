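"""NIPALS partial least squares regression with multiple responses.

Predictors and responses are autoscaled (mean 0, sd 1); latent components are
extracted by the two-block NIPALS iteration with X- and Y-deflation, and the
coefficient matrix is assembled as B = W (P'W)^-1 Q'.  At full predictor rank
the fit coincides with per-response ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlsrModel", "plsr_fit", "plsr_predict", "r2_per_response"]


@dataclass
class PlsrModel:
    n_components: int
    x_weights: np.ndarray  # predictors x components (W)
    x_loadings: np.ndarray  # predictors x components (P)
    y_loadings: np.ndarray  # responses x components (Q)
    x_scores: np.ndarray  # observations x components (T)
    coefficients_std: np.ndarray  # predictors x responses, autoscaled space
    coefficients: np.ndarray  # predictors x responses, original units
    intercept: np.ndarray  # per response, original units
    x_means: np.ndarray
    x_sds: np.ndarray
    y_means: np.ndarray
    y_sds: np.ndarray
    predictor_names: list[str]
    response_names: list[str]
    r2_fitted: dict[str, float]


def _prep(mat, kind: str, names) -> tuple[np.ndarray, list[str]]:
    if hasattr(mat, "columns") and names is None:
        names = [str(c) for c in mat.columns]
    x = np.asarray(mat, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if names is None:
        names = [f"{kind}{i + 1}" for i in range(x.shape[1])]
    if np.isnan(x).any():
        raise ValueError(f"missing values in {kind} matrix")
    sd = x.std(axis=0, ddof=1)
    const = [names[i] for i in np.where(sd == 0)[0]]
    if const:
        raise ValueError(f"constant {kind} column(s): {const}")
    return x, list(names)


def plsr_fit(
    X,
    Y,
    n_components: int = 2,
    predictor_names=None,
    response_names=None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PlsrModel:
    x_raw, pnames = _prep(X, "predictor", predictor_names)
    y_raw, rnames = _prep(Y, "response", response_names)
    if x_raw.shape[0] != y_raw.shape[0]:
        raise ValueError("X and Y must have the same number of observations")
    n, p = x_raw.shape
    q = y_raw.shape[1]
    rank = int(np.linalg.matrix_rank(x_raw - x_raw.mean(axis=0)))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")

    x_means, x_sds = x_raw.mean(axis=0), x_raw.std(axis=0, ddof=1)
    y_means, y_sds = y_raw.mean(axis=0), y_raw.std(axis=0, ddof=1)
    xk = (x_raw - x_means) / x_sds
    yk = (y_raw - y_means) / y_sds

    w_mat = np.zeros((p, n_components))
    p_mat = np.zeros((p, n_components))
    q_mat = np.zeros((q, n_components))
    t_mat = np.zeros((n, n_components))
    for a in range(n_components):
        u = yk[:, int(np.argmax(yk.var(axis=0, ddof=1)))].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = xk.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("degenerate weight vector; Y carries no X signal")
            w /= nw
            t = xk @ w
            qv = yk.T @ t / (t @ t)
            nq = np.linalg.norm(qv)
            u = yk @ qv / (qv @ qv) if nq > 0 else t
            if np.linalg.norm(t - t_old) < tol * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        pv = xk.T @ t / (t @ t)
        xk = xk - np.outer(t, pv)
        yk = yk - np.outer(t, qv)
        w_mat[:, a], p_mat[:, a], q_mat[:, a], t_mat[:, a] = w, pv, qv, t

    b_std = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_mat.T)
    b_orig = (b_std / x_sds[:, None]) * y_sds[None, :]
    intercept = y_means - x_means @ b_orig

    model = PlsrModel(
        n_components=n_components,
        x_weights=w_mat,
        x_loadings=p_mat,
        y_loadings=q_mat,
        x_scores=t_mat,
        coefficients_std=b_std,
        coefficients=b_orig,
        intercept=intercept,
        x_means=x_means,
        x_sds=x_sds,
        y_means=y_means,
        y_sds=y_sds,
        predictor_names=pnames,
        response_names=rnames,
        r2_fitted={},
    )
    model.r2_fitted = r2_per_response(model, x_raw, y_raw)
    return model


def plsr_predict(model: PlsrModel, X_new) -> np.ndarray:
    """Predict responses in original units for new predictor rows."""
    x = np.asarray(X_new, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if hasattr(X_new, "columns"):
        cols = [str(c) for c in X_new.columns]
        if cols != model.predictor_names:
            raise ValueError(
                f"predictor columns {cols} do not match training {model.predictor_names}"
            )
    if x.shape[1] != len(model.predictor_names):
        raise ValueError(
            f"expected {len(model.predictor_names)} predictors, got {x.shape[1]}"
        )
    return x @ model.coefficients + model.intercept


def r2_per_response(model: PlsrModel, X, Y) -> dict[str, float]:
    """R^2 = 1 - SS_res/SS_tot per response, in original units.

    Zero-variance responses map to NaN (undefined).
    """
    y = np.asarray(Y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    pred = plsr_predict(model, X)
    out: dict[str, float] = {}
    for j, name in enumerate(model.response_names):
        ss_tot = float(((y[:, j] - y[:, j].mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = float("nan")
            continue
        ss_res = float(((y[:, j] - pred[:, j]) ** 2).sum())
        out[name] = 1.0 - ss_res / ss_tot
    return out
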