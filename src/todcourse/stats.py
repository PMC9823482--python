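"""Shared enrichment statistics: hypergeometric upper tail and BH-FDR.

The Benjamini-Hochberg implementation accepts a test-family size ``m``
larger than the materialized p-vector, for families (like the 87,360-kmer
dictionary) where most tests sit at p = 1 and are never materialized:
their step-up terms are >= 1 and cannot change any rejection.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

__all__ = ["hypergeom_pvalue", "bh_qvalues"]


def hypergeom_pvalue(foreground: int, list_size: int, background: int, universe: int):
    """Upper-tail P(X >= foreground) drawing ``list_size`` items from a
    ``universe`` containing ``background`` carriers.  Vectorized."""
    fg = np.asarray(foreground)
    return _st.hypergeom.sf(fg - 1, universe, background, list_size)


def bh_qvalues(pvalues, m: int | None = None) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), in the input order.

    ``m`` is the total family size; p-values beyond the materialized vector
    are taken to be 1 (they never affect the step-up minimum below 1).
    """
    p = np.asarray(pvalues, dtype=float)
    k = len(p)
    if k == 0:
        return p.copy()
    m = k if m is None else int(m)
    if m < k:
        raise ValueError("family size m cannot be smaller than len(pvalues)")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(k)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
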