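"""Detection-flag filtering and quantile normalization.

These run before any statistics.  Filtering keeps features called
Present or Marginal in at least a configurable fraction of samples
(array-style detection filter); quantile normalization forces every
sample onto the across-sample mean of sorted value vectors, with tied
values within a sample receiving the mean of the quantile values their
ranks span.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError
from .io import ExpressionMatrix


def filter_detected(
    matrix: ExpressionMatrix,
    min_fraction: float = 0.5,
    strict: bool = False,
    intensity_floor: float | None = None,
) -> ExpressionMatrix:
    """Keep features detected in at least ``min_fraction`` of samples.

    Detection means a Present or Marginal flag; when the matrix carries no
    flags an ``intensity_floor`` (value strictly above the floor counts as
    detected) must be supplied instead.  ``strict=True`` requires the
    fraction to exceed ``min_fraction`` rather than reach it (the
    validation-cohort style "> 80%" rule).  Samples are never removed.
    """
    if not 0 <= min_fraction <= 1:
        raise ConfigError(f"min_fraction must be in [0, 1], got {min_fraction}")
    if matrix.flags is not None:
        detected = matrix.flags.isin(["Present", "Marginal"]).mean(axis=1)
    elif intensity_floor is not None:
        detected = (matrix.values > intensity_floor).mean(axis=1)
    else:
        raise ConfigError(
            "filter_detected: matrix has no detection flags and no "
            "intensity_floor fallback was configured"
        )
    keep = detected > min_fraction if strict else detected >= min_fraction
    kept_ids = matrix.values.index[keep.to_numpy()]
    return matrix.subset_features(kept_ids)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples to the mean of sorted value vectors.

    After normalization every sample's sorted values equal the reference
    (the across-sample mean of sorted vectors); ties within a sample get
    the mean of the reference values at the ranks they occupy, which makes
    the operation deterministic and idempotent.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ConfigError("quantile_normalize needs at least 2 samples")
    if not np.isfinite(X).all():
        raise ParseError("quantile_normalize requires finite values")
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col_ref = np.empty(X.shape[0])
        col_ref[order[:, j]] = ref
        # average the reference over tied input values within the sample
        averaged = pd.Series(col_ref).groupby(X[:, j]).transform("mean")
        out[:, j] = averaged.to_numpy()
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.flags)
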