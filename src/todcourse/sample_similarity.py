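"""Cross-condition QC: sample correlation matrix, classical MDS, and
cycling-set overlaps.

The correlation matrix concatenates every condition's samples over the
common gene set on the log2 scale.  Embedding uses classical (Torgerson)
MDS on the distance ``1 - r`` — the sign of the correlation is informative
between tissues, so ``1 - r**2`` is deliberately not the default.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cycling_detection import CyclingCallSet
from .timecourse_io import TimeCourse

__all__ = [
    "correlation_matrix",
    "mds_embed",
    "cycling_overlaps",
    "venn_counts",
]


def correlation_matrix(tcs: Sequence[TimeCourse], log2: bool = True) -> pd.DataFrame:
    """Product-moment correlation between all samples of all conditions,
    computed on the common gene set (log2 scale by default).

    Sample labels are ``condition:ZT<h>``.
    """
    if not tcs:
        raise ValueError("need at least one time course")
    common = set(tcs[0].gene_ids)
    for tc in tcs[1:]:
        common &= set(tc.gene_ids)
    if not common:
        raise ValueError("no genes shared across the time courses")
    genes = [g for g in tcs[0].gene_ids if g in common]

    cols, labels = [], []
    for tc in tcs:
        idx = [tc.gene_ids.index(g) for g in genes]
        sub = tc.matrix[idx, :]
        if log2:
            sub = np.log2(sub + 1.0)
        cols.append(sub)
        labels.extend(f"{tc.condition}:ZT{z:g}" for z in tc.zt)
    data = np.hstack(cols)
    corr = np.corrcoef(data, rowvar=False)
    return pd.DataFrame(corr, index=labels, columns=labels)


def mds_embed(corr: pd.DataFrame, dims: int = 2):
    """Classical (Torgerson) MDS of samples on the distance ``1 - r``.

    Returns ``(coords, stress)``: a samples x dims frame (axes sign-fixed so
    the largest-magnitude coordinate on each axis is positive, making the
    embedding deterministic up to the inherent rotation degeneracy of
    eigen-decomposition) and the relative stress
    ``sqrt(sum (d_hat - d)^2 / sum d^2)``.
    """
    d = 1.0 - np.asarray(corr, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    for a in range(coords.shape[1]):
        i = np.abs(coords[:, a]).argmax()
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    dhat = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    )
    denom = (d**2).sum()
    stress = float(np.sqrt(((dhat - d) ** 2).sum() / denom)) if denom > 0 else 0.0
    frame = pd.DataFrame(
        coords, index=corr.index, columns=[f"dim{a + 1}" for a in range(coords.shape[1])]
    )
    return frame, stress


def cycling_overlaps(
    callsets: Sequence[CyclingCallSet],
    combos: Sequence[Sequence[str]] | None = None,
) -> dict:
    """Exact cycling-set intersection counts.

    Always reports pairwise counts and the all-condition intersection;
    ``combos`` adds arbitrary k-way combinations by condition name.
    """
    sets = {c.condition: c.rhythmic_genes() for c in callsets}
    names = list(sets)
    pairwise = pd.DataFrame(0, index=names, columns=names)
    for a in names:
        for b in names:
            pairwise.loc[a, b] = len(sets[a] & sets[b])
    out = {
        "sets": sets,
        "pairwise": pairwise,
        "all": frozenset.intersection(*sets.values()) if sets else frozenset(),
    }
    if combos:
        out["combos"] = {
            tuple(combo): len(frozenset.intersection(*(sets[c] for c in combo)))
            for combo in combos
        }
    return out


def venn_counts(sets: Mapping[str, frozenset]) -> dict:
    """Exact Venn cell counts for up to a handful of named sets.

    Keys are membership bit-patterns over the set order (e.g. '110');
    cells sum to the union size.
    """
    names = list(sets)
    fsets = [frozenset(sets[n]) for n in names]
    union = frozenset().union(*fsets) if fsets else frozenset()
    cells = {}
    for item_pattern in range(1, 2 ** len(names)):
        pattern = format(item_pattern, f"0{len(names)}b")
        inc = [s for s, bit in zip(fsets, pattern) if bit == "1"]
        exc = [s for s, bit in zip(fsets, pattern) if bit == "0"]
        cell = frozenset.intersection(*inc)
        for s in exc:
            cell -= s
        cells[pattern] = len(cell)
    cells["names"] = tuple(names)
    cells["union"] = len(union)
    return cells
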