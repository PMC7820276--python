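"""Log2 transformation and quantile normalization of intensity matrices."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .matrix import ExpressionMatrix

__all__ = ["log2_transform", "quantile_normalize"]


def log2_transform(raw: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Convert linear-scale intensities to log2 intensities.

    ``value' = log2(value + offset)``.  ``offset`` is a small positive
    constant guarding against log2(0); the transform is monotone in the
    input.  Negative input intensities are rejected with the offending
    cell named.
    """
    x = raw.values.to_numpy(dtype=float)
    if (x < 0).any():
        gi, si = np.argwhere(x < 0)[0]
        raise ValueError(
            f"negative intensity at gene {raw.gene_ids[gi]!r}, "
            f"sample {raw.sample_ids[si]!r}"
        )
    if offset < 0:
        raise ValueError("offset must be non-negative")
    return raw.copy_with(np.log2(x + offset))


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto a common intensity distribution.

    The reference distribution is the row-wise mean of the per-sample
    sorted value vectors; each column's values are replaced by the
    reference value at their within-column rank, preserving row order.
    Ties receive average ranks and the reference is interpolated at the
    fractional rank, which keeps the operation idempotent and preserves
    the grand mean exactly.
    """
    if m.values.shape[1] < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    x = m.values.to_numpy(dtype=float)
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    grid = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return m.copy_with(out)
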