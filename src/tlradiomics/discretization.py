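"""Post-extraction discretization of radiomic feature values.

Conventional radiomics discretizes voxel intensities *before* feature
extraction; here the extracted feature values themselves are binned,
which keeps the full image information in the features while still
granting the robustness of discretized inputs.  Two schemes:

* **FBN** (fixed bin number, equal frequency): values are ranked
  ascending (competition ranking — tied values share the smallest
  ordinal rank, so ties never straddle a bin boundary) and

      y = ceil( n * (Rank(A(x)) - 1) / (Count(A) - 1) ),   y = 1 at min(A)

* **FBW** (fixed bin width, equal range):

      y = ceil( n * (A(x) - min(A)) / (max(A) - min(A)) ),  y = 1 at min(A)

Outputs are integers in ``[1, n]``.  Fitting stores per-feature state
(min/max for FBW, the sorted training values for FBN) so held-out
samples can be binned without touching their own distribution
(leakage-safe ``apply``): new FBW values are clipped into ``[1, n]``;
new FBN values take the rank of the largest training value not
exceeding them (below the training minimum -> bin 1, above the training
maximum -> bin n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .table import FeatureTable

logger = logging.getLogger("tlradiomics")

METHODS = ("none", "fbn", "fbw")

#: tolerance subtracted before the ceiling so an exactly-integral bin
#: boundary reached through floating-point arithmetic is not promoted
#: to the next bin
_CEIL_TOL = 1e-12


@dataclass
class DiscretizerModel:
    """Fitted per-feature binning state enabling leakage-safe transform."""

    method: str                       # none | fbn | fbw
    n_bins: int
    feature_ids: list = field(default_factory=list)
    # FBW state
    minima: pd.Series | None = None
    maxima: pd.Series | None = None
    # FBN state: sorted training values per feature (column-aligned matrix)
    sorted_train: np.ndarray | None = None
    n_train: int = 0


def _ceil_tol(v: np.ndarray) -> np.ndarray:
    return np.ceil(v - _CEIL_TOL)


def _fbn_bins(values: np.ndarray, n: int) -> np.ndarray:
    """FBN formula for one feature column given competition ranks."""
    count = values.shape[0]
    if count < 2:
        return np.ones(count)
    ranks = rankdata(values, method="min")
    y = _ceil_tol(n * (ranks - 1.0) / (count - 1.0))
    y[values == values.min()] = 1.0       # stated special case at min(A)
    return np.clip(y, 1, n)


def _fbw_bins(values: np.ndarray, lo: float, hi: float, n: int) -> np.ndarray:
    if hi <= lo:                          # constant feature: max = min
        return np.ones(values.shape[0])
    y = _ceil_tol(n * (values - lo) / (hi - lo))
    y[values <= lo] = 1.0
    return np.clip(y, 1, n)


def _validate_bins(n: int) -> None:
    if int(n) < 1:
        raise ValueError("number of bins must be >= 1")


def fbn_fit_transform(table: FeatureTable, n: int
                      ) -> tuple[FeatureTable, DiscretizerModel]:
    """Equal-frequency (rank) discretization into ``n`` bins per feature."""
    _validate_bins(n)
    x = table.matrix()
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = _fbn_bins(x[:, j], n)
    model = DiscretizerModel(
        method="fbn", n_bins=int(n), feature_ids=list(table.feature_ids),
        sorted_train=np.sort(x, axis=0), n_train=x.shape[0])
    return table.with_values(out, note=f"FBN{n} discretized"), model


def fbw_fit_transform(table: FeatureTable, n: int
                      ) -> tuple[FeatureTable, DiscretizerModel]:
    """Equal-width discretization into ``n`` bins per feature."""
    _validate_bins(n)
    x = table.matrix()
    lo, hi = x.min(axis=0), x.max(axis=0)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = _fbw_bins(x[:, j], lo[j], hi[j], n)
    fids = list(table.feature_ids)
    model = DiscretizerModel(
        method="fbw", n_bins=int(n), feature_ids=fids,
        minima=pd.Series(lo, index=fids), maxima=pd.Series(hi, index=fids))
    return table.with_values(out, note=f"FBW{n} discretized"), model


def fit_transform(table: FeatureTable, method: str, n: int = 32
                  ) -> tuple[FeatureTable, DiscretizerModel]:
    """Dispatch on ``method`` in {none, fbn, fbw}."""
    method = method.lower()
    if method == "none":
        return table, DiscretizerModel(method="none", n_bins=0)
    if method == "fbn":
        return fbn_fit_transform(table, n)
    if method == "fbw":
        return fbw_fit_transform(table, n)
    raise ValueError(f"unknown discretization method {method!r}; "
                     f"choose from {METHODS}")


def discretize_apply(model: DiscretizerModel, table: FeatureTable
                     ) -> FeatureTable:
    """Bin new samples with a previously fitted model.

    FBW uses the stored min/max and clips into ``[1, n]``.  FBN assigns
    each new value the competition rank of the largest training value
    not exceeding it, then applies the formula with the training count.
    """
    if model.method == "none":
        return table
    missing = [f for f in table.feature_ids if f not in set(model.feature_ids)]
    if missing:
        raise KeyError(f"feature {missing[0]!r} was not fitted")
    cols = [model.feature_ids.index(f) for f in table.feature_ids]
    x = table.matrix()
    n = model.n_bins
    out = np.empty_like(x)

    if model.method == "fbw":
        lo = model.minima.loc[table.feature_ids].to_numpy()
        hi = model.maxima.loc[table.feature_ids].to_numpy()
        for j in range(x.shape[1]):
            out[:, j] = _fbw_bins(x[:, j], lo[j], hi[j], n)
        return table.with_values(out, note=f"FBW{n} applied (frozen fit)")

    count = model.n_train
    for jt, jm in enumerate(cols):
        train = model.sorted_train[:, jm]
        v = x[:, jt]
        if count < 2:
            out[:, jt] = 1.0
            continue
        # number of training values <= v; 0 means below training minimum
        c = np.searchsorted(train, v, side="right")
        below = c == 0
        c_safe = np.maximum(c, 1)
        # competition rank of the largest training value <= v
        ranks = np.searchsorted(train, train[c_safe - 1], side="left") + 1
        y = _ceil_tol(n * (ranks - 1.0) / (count - 1.0))
        y = np.clip(y, 1, n)
        y[below] = 1.0
        y[v > train[-1]] = n
        y[v == train[0]] = 1.0
        out[:, jt] = y
    return table.with_values(out, note=f"FBN{n} applied (frozen fit)")
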