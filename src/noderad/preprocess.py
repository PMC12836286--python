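"""Leak-free preprocessing: Min-Max scaling and SMOTE oversampling.

Both are fitted strictly on training rows.  Within a cross-validation
iteration the order is: fit the scaler on raw training rows, transform
training and test rows with those factors, then oversample the scaled
training rows with SMOTE -- nearest neighbours are only meaningful on a
common scale.

Test values outside the training range are deliberately NOT clipped, so
transformed test features may fall outside [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ScalerParams:
    """Per-feature (min, max) learned from training rows only."""

    columns: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    @property
    def constant_columns(self) -> tuple[str, ...]:
        return tuple(
            c for c, lo, hi in zip(self.columns, self.mins, self.maxs) if lo == hi
        )


def fit_minmax(train: pd.DataFrame, columns=None) -> ScalerParams:
    """Learn per-column minima and maxima from training rows."""
    if len(train) == 0:
        raise ValidationError("cannot fit scaler on an empty table")
    cols = tuple(columns) if columns is not None else tuple(train.columns)
    sub = train[list(cols)].to_numpy(dtype=float)
    params = ScalerParams(columns=cols, mins=sub.min(axis=0), maxs=sub.max(axis=0))
    if params.constant_columns:
        logger.warning("constant training columns: %s", params.constant_columns)
    return params


def apply_minmax(params: ScalerParams, table: pd.DataFrame) -> pd.DataFrame:
    """Map x -> (x - min) / (max - min) per column; constants map to 0."""
    missing = [c for c in params.columns if c not in table.columns]
    if missing:
        raise ValidationError(f"columns missing from table: {missing}")
    out = table.copy()
    span = params.maxs - params.mins
    x = out[list(params.columns)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (x - params.mins) / span
    scaled[:, span == 0] = 0.0
    out[list(params.columns)] = scaled
    return out


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balance classes by interpolated synthetic minority samples.

    Each synthetic sample is ``x_i + u * (x_nn - x_i)`` with
    ``u ~ U(0, 1)`` and ``x_nn`` one of the ``k`` nearest minority
    neighbours (Euclidean) of a randomly drawn minority row ``x_i``.
    Sampling continues until class counts are equal.

    Returns ``(X_out, y_out, synthetic_flag)``; original rows come
    first, unchanged.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("SMOTE requires exactly two classes")
    n_real = len(y)
    flags = np.zeros(n_real, dtype=bool)
    if counts[0] == counts[1]:
        return X.copy(), y.copy(), flags
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if len(Xm) < 2:
        raise ValidationError("SMOTE needs at least 2 minority samples")
    if k >= len(Xm):
        k = len(Xm) - 1
        logger.warning("SMOTE k reduced to %d (minority size %d)", k, len(Xm))

    # k nearest minority neighbours of each minority row (excluding self)
    d2 = cdist(Xm, Xm, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]

    base = rng.integers(0, len(Xm), n_needed)
    pick = rng.integers(0, k, n_needed)
    u = rng.random(n_needed)
    neigh = nn[base, pick]
    X_syn = Xm[base] + u[:, None] * (Xm[neigh] - Xm[base])

    X_out = np.vstack([X, X_syn])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    flag_out = np.concatenate([flags, np.ones(n_needed, dtype=bool)])
    return X_out, y_out, flag_out
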