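"""Quantile normalization across the samples of one time course.

After normalization every sample (column) has exactly the same sorted value
vector: the per-rank mean of the input samples' sorted vectors.  Tied values
within a sample receive the mean of the reference values at their tied
ranks, the standard convention.  Normalization is applied per condition;
cross-condition comparisons downstream use phases, not intensities.
"""

from __future__ import annotations

import logging

import numpy as np

from .timecourse_io import TimeCourse

logger = logging.getLogger(__name__)

__all__ = ["quantile_normalize", "quantile_normalize_matrix"]


def quantile_normalize_matrix(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of a genes x samples matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if np.any(m < 0):
        raise ValueError("negative intensities are not allowed")
    ref = np.sort(m, axis=0).mean(axis=1)  # per-rank mean of sorted columns
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        col = m[:, j]
        uniq, counts = np.unique(col, return_counts=True)
        if len(uniq) == 1:
            logger.warning("sample %d is constant; all values mapped to ref mean", j)
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        # mean of the reference values occupying each tied value's rank block
        tied_means = np.add.reduceat(ref, starts) / counts
        out[:, j] = tied_means[np.searchsorted(uniq, col)]
    return out


def quantile_normalize(tc: TimeCourse) -> TimeCourse:
    """Return a new :class:`TimeCourse` with quantile-normalized samples."""
    return tc.with_matrix(quantile_normalize_matrix(tc.matrix))
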