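"""SPXY calibration/prediction partitioning.

Kennard–Stone farthest-point accretion on the joint distance

    d_xy(p, q) = d_x(p, q) / max d_x + d_y(p, q) / max d_y,

with Euclidean distance on spectra and absolute difference on the Brix
response, so the calibration set covers both predictor and response space
uniformly.  The first two calibration picks are the pair at maximal joint
distance; each subsequent pick maximizes its minimum distance to the
samples already selected.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from ..errors import InvalidParameterError
from .preprocess import SpectraSet

__all__ = ["spxy_split", "spxy_indices", "joint_distance_matrix"]


def joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normalized sum of spectral and response distance matrices."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    dx_max, dy_max = dx.max(), dy.max()
    if dx_max == 0 or dy_max == 0:
        raise InvalidParameterError("identical samples; SPXY distances are degenerate")
    return dx / dx_max + dy / dy_max


def spxy_indices(X: np.ndarray, y: np.ndarray, n_cal: int) -> tuple[np.ndarray, np.ndarray]:
    """Kennard–Stone accretion on the joint distance; returns sorted
    (calibration, prediction) index arrays."""
    d = joint_distance_matrix(X, y)
    n = d.shape[0]
    if not 2 <= n_cal < n:
        raise InvalidParameterError("need 2 <= n_cal < N")
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [int(i), int(j)]
    min_dist = np.minimum(d[i], d[j])
    min_dist[selected] = -1.0
    while len(selected) < n_cal:
        k = int(np.argmax(min_dist))
        selected.append(k)
        min_dist = np.minimum(min_dist, d[k])
        min_dist[k] = -1.0
    cal = np.sort(np.asarray(selected))
    pred = np.setdiff1d(np.arange(n), cal)
    return cal, pred


def spxy_split(
    spectra: SpectraSet, ratio: tuple[int, int] = (3, 1)
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a reference-labelled spectra set, calibration count
    ``round(N * cal / (cal + pred))`` (a 3:1 split of 168 samples gives
    126 / 42)."""
    if spectra.brix is None:
        raise InvalidParameterError("SPXY requires reference Brix values")
    n = spectra.n_samples
    if n < 4:
        raise InvalidParameterError("need at least 4 samples to split")
    c, p = ratio
    if c <= 0 or p <= 0:
        raise InvalidParameterError("ratio parts must be positive")
    n_cal = int(round(n * c / (c + p)))
    n_cal = min(max(n_cal, 2), n - 1)
    return spxy_indices(spectra.reflectance, spectra.brix, n_cal)
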