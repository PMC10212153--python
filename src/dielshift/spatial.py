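"""Moran's I permutation test for spatial autocorrelation of per-station
nocturnality.

I = (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2 with
W the total weight. Expected value under no autocorrelation is -1/(n-1); the
p-value comes from random permutations of station labels, two-sided around
that expectation. Default weights: row-standardised inverse distance;
k-nearest-neighbour weights available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["SpatialWeightMatrix", "MoranResult", "build_weights", "morans_i"]


@dataclass(frozen=True)
class SpatialWeightMatrix:
    station_ids: Sequence
    weights: np.ndarray  # (n, n), zero diagonal
    scheme: str

    def __post_init__(self):
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if (np.diag(w) != 0).any():
            raise ValueError("weight diagonal must be zero")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def zero_rows(self) -> np.ndarray:
        """Indices of stations with no neighbours (all-zero weight rows)."""
        return np.flatnonzero(self.weights.sum(axis=1) == 0)


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    n_permutations: int
    scheme: str
    seed: Optional[int] = None


def build_weights(stations: pd.DataFrame, scheme: str = "inverse_distance",
                  k: int = 5, row_standardize: bool = True) -> SpatialWeightMatrix:
    """Spatial weights from station coordinates (columns ``x``, ``y``).

    ``inverse_distance``: w_ij = 1/d_ij (coincident stations are an error);
    ``knn``: w_ij = 1 for the k nearest neighbours of i (symmetrised by
    union before any row-standardisation).
    """
    ids = list(stations["station_id"])
    xy = stations[["x", "y"]].to_numpy(dtype=float)
    n = len(xy)
    if n < 3:
        raise ValueError("need at least 3 stations")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    off = ~np.eye(n, dtype=bool)
    if scheme == "inverse_distance":
        if (d[off] == 0).any():
            raise ValueError("coincident stations give zero pairwise distance")
        w = np.zeros_like(d)
        w[off] = 1.0 / d[off]
    elif scheme == "knn":
        w = np.zeros_like(d)
        order = np.argsort(d + np.where(off, 0.0, np.inf), axis=1)
        for i in range(n):
            w[i, order[i, :k]] = 1.0
        w = np.maximum(w, w.T)  # symmetrise before standardisation
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    label = scheme + ("_row_standardized" if row_standardize else "")
    if row_standardize:
        sums = w.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(sums > 0, w / sums, 0.0)
    return SpatialWeightMatrix(station_ids=ids, weights=w, scheme=label)


def _moran_stat(z: np.ndarray, w: np.ndarray, W: float) -> float:
    n = len(z)
    return float(n / W * (z @ w @ z) / (z @ z))


def morans_i(values, weights: SpatialWeightMatrix, n_permutations: int = 999,
             seed: Optional[int] = None) -> MoranResult:
    """Moran's I with a two-sided permutation p-value.

    ``values`` are one number per station, ordered like
    ``weights.station_ids``; constant values are an error. The p-value is the
    rank of |I_obs - E[I]| among permuted |I - E[I]| (add-one rule).
    """
    x = np.asarray(values, dtype=float)
    w = weights.weights
    n = len(x)
    if n != w.shape[0]:
        raise ValueError("values length does not match weight matrix")
    z = x - x.mean()
    if np.allclose(z, 0):
        raise ValueError("constant values have zero variance; Moran's I undefined")
    W = float(w.sum())
    i_obs = _moran_stat(z, w, W)
    e_i = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    # vectorised: permute z in blocks, reuse the quadratic form
    block = 200
    done = 0
    while done < n_permutations:
        m = min(block, n_permutations - done)
        Z = np.stack([rng.permutation(z) for _ in range(m)], axis=1)  # (n, m)
        num = np.einsum("im,im->m", Z, w @ Z)
        den = np.einsum("im,im->m", Z, Z)
        perms[done:done + m] = n / W * num / den
        done += m
    extreme = np.abs(perms - e_i) >= abs(i_obs - e_i) - 1e-15
    p = (1.0 + extreme.sum()) / (n_permutations + 1.0)
    return MoranResult(I=i_obs, expected_I=e_i, p_value=float(p),
                       n_permutations=n_permutations, scheme=weights.scheme, seed=seed)
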