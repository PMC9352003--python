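"""Seeded comparison of full-spectrum PLS, SPA-PLS and CARS-PLS on
simulated spectra — the desk-scale analogue of a physical calibration
transfer study.

Each replicate simulates a 168-sample population on the 1771-point grid,
decimates to 591 wavelengths, applies MSC then SNV, partitions 3:1 by
SPXY, and fits the three models on the calibration set.  Reported metrics
are computed on the held-out prediction set.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from ..synthfruit import SpectraSpec, simulate_spectra
from .pls import evaluate_model, pls_fit, select_ncomp_cv
from .preprocess import downsample_wavelengths, msc, snv
from .selection import cars_select, spa_select
from .split import spxy_split

__all__ = ["benchmark_once", "run_brix_benchmark"]


def benchmark_once(
    seed: int,
    spec: SpectraSpec | None = None,
    keep_every: int = 3,
    max_components: int = 15,
    n_folds: int = 5,
    cars_runs: int = 50,
    spa_range: tuple[int, int] = (30, 50),
) -> dict:
    """One seeded replicate; returns per-method metrics and subset sizes."""
    sspec = replace(spec or SpectraSpec(), seed=seed)
    sset, _ = simulate_spectra(sspec)
    sset = snv(msc(downsample_wavelengths(sset, keep_every)))
    cal, pred = spxy_split(sset, (3, 1))
    X, y = sset.reflectance, sset.brix
    Xc, yc, Xp, yp = X[cal], y[cal], X[pred], y[pred]

    out = {"seed": seed, "n_cal": len(cal), "n_pred": len(pred)}

    def _fit_eval(Xsel_c, Xsel_p, tag, n_vars):
        ncomp, _ = select_ncomp_cv(
            Xsel_c, yc, max_components=min(max_components, n_vars), n_folds=n_folds, seed=seed
        )
        model = pls_fit(Xsel_c, yc, ncomp)
        m = evaluate_model(model, Xsel_c, yc, Xsel_p, yp)
        out[f"{tag}_rc"] = m.r_c
        out[f"{tag}_rmsec"] = m.rmsec
        out[f"{tag}_rp"] = m.r_p
        out[f"{tag}_rmsep"] = m.rmsep
        out[f"{tag}_ncomp"] = ncomp
        out[f"{tag}_nvars"] = n_vars

    _fit_eval(Xc, Xp, "full", X.shape[1])

    cars = cars_select(Xc, yc, n_runs=cars_runs, n_folds=n_folds, seed=seed)
    ci = cars.selected_indices
    _fit_eval(Xc[:, ci], Xp[:, ci], "cars", len(ci))

    spa = spa_select(Xc, yc, *spa_range, n_folds=n_folds, seed=seed)
    si = spa.selected_indices
    _fit_eval(Xc[:, si], Xp[:, si], "spa", len(si))
    return out


def run_brix_benchmark(seeds, spec: SpectraSpec | None = None, **kwargs) -> pd.DataFrame:
    """Run :func:`benchmark_once` over ``seeds``; one row per replicate."""
    return pd.DataFrame([benchmark_once(int(s), spec=spec, **kwargs) for s in seeds])
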