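"""Expression and methylation matrix filters and transforms.

Expression matrices arrive on a raw non-negative scale: lncRNAs that are zero
in every sample are dropped, remaining zeros are replaced by the smallest
positive value of the matrix, and everything is log2-transformed.  Beta-value
matrices only lose probes that are missing in every sample; partially missing
probes are kept.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def filter_zero_genes(expr: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop genes whose expression is 0 in every sample.

    Returns the filtered matrix (row order preserved) and the removed count.
    Raises if nothing survives.
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("raw expression matrix contains negative values")
    all_zero = (expr == 0).all(axis=1)
    kept = expr.loc[~all_zero]
    if kept.empty:
        raise ValueError("all genes are zero in every sample")
    n_removed = int(all_zero.sum())
    if n_removed:
        log.info("filter_zero_genes: removed %d all-zero genes", n_removed)
    return kept, n_removed


def min_positive(expr: pd.DataFrame) -> float:
    """Smallest strictly positive value of the matrix."""
    values = expr.to_numpy()
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError("matrix has no positive values")
    return float(pos.min())


def log2_with_zero_replacement(expr: pd.DataFrame,
                               floor: float | None = None) -> pd.DataFrame:
    """Replace zeros with the matrix minimum positive value, then log2.

    ``floor`` overrides the replacement value, so the same minimum can be
    shared across the tumor and normal matrices of one dataset.  The output
    contains no NA or -inf.  Monotone: ordering of values is preserved, with
    ties created only at the replaced minimum.
    """
    if floor is None:
        floor = min_positive(expr)
    if floor <= 0:
        raise ValueError("replacement floor must be positive")
    values = expr.to_numpy(dtype=float, copy=True)
    values[values == 0] = floor
    return pd.DataFrame(np.log2(values), index=expr.index, columns=expr.columns)


def filter_all_na_probes(beta: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop probes that are NA in every sample; keep partially-NA probes."""
    all_na = beta.isna().all(axis=1)
    kept = beta.loc[~all_na]
    n_removed = int(all_na.sum())
    if n_removed:
        log.info("filter_all_na_probes: removed %d all-NA probes", n_removed)
    return kept, n_removed


def validate_beta(beta: pd.DataFrame) -> None:
    """Check all non-NA beta values lie in [0, 1]."""
    values = beta.to_numpy()
    ok = np.isnan(values) | ((values >= 0) & (values <= 1))
    if not ok.all():
        bad = values[~ok]
        raise ValueError(
            f"beta matrix has {bad.size} values outside [0, 1] "
            f"(e.g. {bad.flat[0]!r})")
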