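"""Characteristic-wavelength selection: CARS and SPA.

CARS (competitive adaptive reweighted sampling) wraps PLS in a
survival-of-the-fittest loop: each run fits PLS on a Monte-Carlo row
subsample, treats absolute regression coefficients as fitness weights,
force-retains the strongest variables under an exponentially decreasing
schedule (all W variables survive run 1, two survive the last run), and
resamples the next subset by adaptive reweighted sampling.  The subset
whose cross-validated RMSE is minimal over all runs is returned.

SPA (successive projections algorithm) is a deterministic forward chain:
starting from a candidate column, each step adds the column with the
largest norm after orthogonal projection onto the complement of the span
of the columns already chosen, which keeps collinearity among the selected
wavelengths minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..errors import InvalidParameterError
from .pls import _folds, pls_fit, rmsecv

__all__ = ["SelectionResult", "cars_select", "spa_select", "spa_chain", "edf_schedule"]


@dataclass(frozen=True)
class SelectionResult:
    """A selected wavelength-index subset with its error trace."""

    selected_indices: np.ndarray  # sorted, unique
    criterion_trace: np.ndarray  # per-iteration RMSECV (CARS) or per-k RMSE (SPA)
    best_iteration: int
    method: str  # "CARS" | "SPA"
    n_selected_trace: np.ndarray | None = None  # CARS: subset size per run


def edf_schedule(n_wavelengths: int, n_runs: int) -> np.ndarray:
    """Forced-retention counts per run: ``round(r_i * W)`` with
    ``r_i = a exp(-k i)`` calibrated so run 1 keeps all W variables and the
    last run keeps 2.  Non-increasing by construction."""
    w = n_wavelengths
    a = (w / 2.0) ** (1.0 / (n_runs - 1))
    k = math.log(w / 2.0) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    counts = np.rint(a * np.exp(-k * i) * w).astype(int)
    return np.clip(counts, 2, w)


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    n_folds: int = 10,
    seed: int | None = 0,
    mc_fraction: float = 0.8,
    max_components: int = 10,
) -> SelectionResult:
    """CARS wavelength selection; returns the minimal-RMSECV subset."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, w = X.shape
    if n_runs < 2:
        raise InvalidParameterError("n_runs must be >= 2")
    if w < 10:
        raise InvalidParameterError("CARS needs at least 10 wavelengths")
    if not 0 < mc_fraction <= 1:
        raise InvalidParameterError("mc_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    folds = _folds(n, n_folds, None if seed is None else int(rng.integers(2**31 - 1)))
    schedule = edf_schedule(w, n_runs)
    n_rows = max(3, int(round(mc_fraction * n)))

    current = np.arange(w)
    subsets: list[np.ndarray] = []
    trace: list[float] = []
    sizes: list[int] = []
    for i, k_i in enumerate(schedule):
        rows = rng.choice(n, size=min(n_rows, n), replace=False)
        ncomp = min(max_components, len(current), len(rows) - 1)
        model = pls_fit(X[np.ix_(rows, current)], y[rows], ncomp)
        weights = np.abs(model.regression_coefficients)

        # forced retention: the EDF schedule caps the surviving count
        keep = min(int(k_i), len(current))
        top = np.argsort(weights)[::-1][:keep]
        current, pw = current[top], weights[top]
        if len(current) < 2:
            break
        cv_comp = min(max_components, len(current))
        trace.append(rmsecv(X[:, current], y, cv_comp, folds))
        subsets.append(current.copy())
        sizes.append(len(current))

        # adaptive reweighted sampling: the next run's subset is drawn
        # without replacement, survival probability proportional to |coef|
        if i + 1 < len(schedule):
            size = min(int(schedule[i + 1]), len(current))
            if pw.sum() <= 0:
                pw = np.ones_like(pw)
            pick = rng.choice(len(current), size=size, replace=False, p=pw / pw.sum())
            current = current[pick]
            if len(current) < 2:
                break

    best = int(np.argmin(trace))
    return SelectionResult(
        selected_indices=np.sort(subsets[best]),
        criterion_trace=np.asarray(trace),
        best_iteration=best,
        method="CARS",
        n_selected_trace=np.asarray(sizes),
    )


def spa_chain(X: np.ndarray, start: int, k: int, tol: float = 1e-10) -> list[int]:
    """Forward projection chain of up to ``k`` column indices from ``start``.

    Stops early if every remaining column is (numerically) inside the span
    of the selected ones — e.g. a duplicated column projects to zero and is
    never chosen."""
    Xp = np.array(X, dtype=float)
    scale = float(np.linalg.norm(Xp)) or 1.0
    sel = [int(start)]
    v = Xp[:, start].copy()
    for _ in range(k - 1):
        denom = float(v @ v)
        if denom <= (tol * scale) ** 2:
            break
        Xp -= np.outer(v, (v @ Xp) / denom)
        norms = np.linalg.norm(Xp, axis=0)
        norms[sel] = -1.0
        j = int(np.argmax(norms))
        if norms[j] <= tol * scale:
            break
        sel.append(j)
        v = Xp[:, j].copy()
    return sel


def _ols_rmse(X: np.ndarray, y: np.ndarray, train, test) -> float:
    A = np.column_stack([np.ones(len(train)), X[train]])
    beta, *_ = np.linalg.lstsq(A, y[train], rcond=None)
    pred = np.column_stack([np.ones(len(test)), X[test]]) @ beta
    return float(np.sum((y[test] - pred) ** 2))


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    k_min: int = 30,
    k_max: int = 50,
    n_folds: int = 10,
    seed: int | None = 0,
    starts: np.ndarray | None = None,
) -> SelectionResult:
    """SPA selection with the subset size scanned over ``[k_min, k_max]``.

    Chains are grown from every candidate start column (all columns by
    default); the chain with the lowest calibration RMSE at ``k_max`` is
    kept, and its prefixes are scored by cross-validated RMSE of a linear
    model to pick the subset size."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, w = X.shape
    if k_max > w:
        raise InvalidParameterError("k_max cannot exceed the number of wavelengths")
    if not 1 <= k_min <= k_max:
        raise InvalidParameterError("need 1 <= k_min <= k_max")
    Xc = X - X.mean(axis=0)
    cand = np.arange(w) if starts is None else np.asarray(starts, dtype=int)

    best_chain, best_sse = None, np.inf
    all_idx = np.arange(n)
    for s in cand:
        chain = spa_chain(Xc, int(s), k_max)
        if len(chain) < k_min:
            continue
        sse = _ols_rmse(X[:, chain], y, all_idx, all_idx)
        if sse < best_sse:
            best_sse, best_chain = sse, chain
    if best_chain is None:
        raise InvalidParameterError("no chain reached k_min columns; data too collinear")

    folds = _folds(n, n_folds, seed)
    ks = np.arange(k_min, min(k_max, len(best_chain)) + 1)
    trace = []
    for k in ks:
        cols = best_chain[:k]
        press = sum(_ols_rmse(X[:, cols], y, tr, te) for tr, te in folds)
        trace.append(math.sqrt(press / n))
    best = int(np.argmin(trace))
    return SelectionResult(
        selected_indices=np.sort(np.asarray(best_chain[: ks[best]])),
        criterion_trace=np.asarray(trace),
        best_iteration=best,
        method="SPA",
    )
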