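"""Single-response partial least squares (PLS1) regression.

The NIPALS deflation scheme is used: at each step the weight vector is the
(normalized) cross-covariance ``X' y``, scores are ``t = X w``, loadings
``p = X' t / t't`` and ``q = y' t / t't``, after which both blocks are
deflated.  With a single response no inner iteration is required and the
algorithm is exact.  Prediction is affine in the input spectrum through the
collapsed coefficient vector ``B = W (P' W)^{-1} q``.

Only mean-centering is applied internally — scatter correction (MSC/SNV)
is expected to have normalized the spectra already.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from ..errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "PlsModel",
    "ModelMetrics",
    "pls_fit",
    "select_ncomp_cv",
    "evaluate_model",
    "rmse",
]


@dataclass(frozen=True)
class PlsModel:
    n_components: int
    x_weights: np.ndarray  # (W, A)
    x_loadings: np.ndarray  # (W, A)
    y_loadings: np.ndarray  # (A,)
    regression_coefficients: np.ndarray  # (W,)
    x_mean: np.ndarray  # (W,)
    y_mean: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.regression_coefficients + self.y_mean


@dataclass(frozen=True)
class ModelMetrics:
    """Calibration / prediction correlation and RMSE (degrees Brix).

    A zero-variance truth or prediction vector leaves the corresponding
    correlation undefined; it is reported as NaN while the RMSE is still
    computed."""

    r_c: float
    rmsec: float
    r_p: float
    rmsep: float


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PlsModel:
    """Fit a PLS1 model with ``n_components`` latent variables."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, w = X.shape
    if len(y) != n:
        raise InvalidParameterError("X and y sample counts differ")
    if not 1 <= n_components <= min(n - 1, w):
        raise InvalidParameterError(
            f"n_components must lie in [1, min(N-1, W)] = [1, {min(n - 1, w)}]"
        )
    if np.ptp(y) == 0:
        raise DegenerateInputError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean

    Ws, Ps, Qs = [], [], []
    for _ in range(n_components):
        wv = Xr.T @ yr
        nrm = np.linalg.norm(wv)
        if nrm <= np.finfo(float).eps * max(n, w):
            break  # X residual no longer covaries with y
        wv = wv / nrm
        t = Xr @ wv
        tt = float(t @ t)
        if tt <= 0:
            break
        p = Xr.T @ t / tt
        q = float(yr @ t) / tt
        Xr = Xr - np.outer(t, p)
        yr = yr - q * t
        Ws.append(wv)
        Ps.append(p)
        Qs.append(q)

    W_ = np.column_stack(Ws)
    P_ = np.column_stack(Ps)
    q_ = np.array(Qs)
    coef = W_ @ np.linalg.solve(P_.T @ W_, q_)
    return PlsModel(
        n_components=W_.shape[1],
        x_weights=W_,
        x_loadings=P_,
        y_loadings=q_,
        regression_coefficients=coef,
        x_mean=x_mean,
        y_mean=y_mean,
    )


def rmse(truth: np.ndarray, pred: np.ndarray) -> float:
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    return float(np.sqrt(np.mean((truth - pred) ** 2)))


def _folds(n: int, n_folds: int, seed: int | None):
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    folds,
) -> float:
    """Cross-validated RMSE of a PLS1 model over precomputed folds."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    press = 0.0
    for train, test in folds:
        a = min(n_components, len(train) - 1, X.shape[1])
        model = pls_fit(X[train], y[train], a)
        press += float(np.sum((y[test] - model.predict(X[test])) ** 2))
    return float(np.sqrt(press / len(y)))


def select_ncomp_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 20,
    n_folds: int = 10,
    seed: int | None = 0,
) -> tuple[int, np.ndarray]:
    """Pick the latent-variable count minimizing k-fold RMSECV.

    Folds are shuffled once from ``seed`` and shared across component
    counts, so the trace (and hence the choice) is deterministic."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if max_components < 1:
        raise InvalidParameterError("max_components must be >= 1")
    if n_folds < 2 or n_folds > len(y):
        raise InvalidParameterError("need 2 <= n_folds <= N")
    folds = _folds(len(y), n_folds, seed)
    upper = min(max_components, X.shape[1], len(y) - int(np.ceil(len(y) / n_folds)) - 1)
    upper = max(upper, 1)
    trace = np.array([rmsecv(X, y, a, folds) for a in range(1, upper + 1)])
    return int(np.argmin(trace)) + 1, trace


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_model(
    model: PlsModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
) -> ModelMetrics:
    """Pearson correlation and RMSE on calibration and prediction sets."""
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_pred) == 0:
        raise InvalidParameterError("prediction set is empty")
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    yc_hat = model.predict(X_cal)
    yp_hat = model.predict(X_pred)
    return ModelMetrics(
        r_c=_pearson(y_cal, yc_hat),
        rmsec=rmse(y_cal, yc_hat),
        r_p=_pearson(y_pred, yp_hat),
        rmsep=rmse(y_pred, yp_hat),
    )
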