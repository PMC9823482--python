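"""Template-correlation rhythmicity detection and phase assignment.

A library of 24 h-periodic model templates (several waveform shapes at every
hourly phase offset, standardized on the sampling grid) is correlated
against each expressed gene's log2 profile.  A gene is called rhythmic when
its best product-moment correlation reaches ``r_min`` (default 0.8, the
empirically established cutoff for two-day, 2-hourly designs), and its
phase — the time of day (TOD) of peak expression — is the best template's
phase offset in ZT-label space.

The expressed/not-expressed gate precedes rhythmicity: a gene counts as
expressed when at least ``min_consecutive`` consecutive samples exceed a
background threshold taken as a low quantile of the whole matrix.
Summaries follow the mixed-denominator reporting convention of cycling
surveys: not-expressed and not-rhythmic percentages are of the total gene
count, the rhythmic percentage is of expressed genes, each rounded to the
nearest integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import waveforms
from .timecourse_io import TimeCourse

logger = logging.getLogger(__name__)

__all__ = [
    "ModelLibrary",
    "CyclingCallSet",
    "build_model_library",
    "call_expressed",
    "detect_cycling",
    "summarize_calls",
    "summarize_counts",
    "phase_lists",
]

DEFAULT_R_MIN = 0.8


@dataclass(frozen=True)
class ModelLibrary:
    """Standardized period-24 templates evaluated on the ZT grid.

    Templates are ordered phase-major (phase 0 shapes first), which makes a
    first-maximum argmax resolve ties toward the earlier phase, then the
    configured shape order.
    """

    zt: np.ndarray
    shapes: tuple
    phases: np.ndarray
    templates: np.ndarray  # (n_templates, n_samples), zero mean, unit variance
    meta: tuple  # tuple of (shape, phase) aligned with templates rows

    def __len__(self) -> int:
        return self.templates.shape[0]


def build_model_library(
    zt_grid: Sequence[float],
    shapes: Sequence[str] = waveforms.DEFAULT_SHAPES,
    phase_step: float = 1.0,
) -> ModelLibrary:
    """Build the template library on ``zt_grid`` (must span >= 2 full cycles)."""
    zt = np.asarray(zt_grid, dtype=float)
    if zt[-1] - zt[0] < 48.0:
        raise ValueError("zt grid must cover at least two full 24 h cycles")
    if np.max(np.diff(zt)) > 6.0:
        raise ValueError("grid spacing > 6 h: insufficient sampling for 24 h models")
    phases = np.arange(0.0, 24.0, phase_step)
    rows, meta = [], []
    for phase in phases:
        for shape in shapes:
            y = waveforms.evaluate(shape, zt, phase)
            sd = y.std()
            if sd < 1e-12:
                raise ValueError(
                    f"template {shape}@{phase:g} is constant on this grid"
                )
            rows.append((y - y.mean()) / sd)
            meta.append((shape, float(phase)))
    return ModelLibrary(
        zt=zt,
        shapes=tuple(shapes),
        phases=phases,
        templates=np.vstack(rows),
        meta=tuple(meta),
    )


def call_expressed(
    tc: TimeCourse,
    background_quantile: float = 0.2,
    min_consecutive: int = 2,
) -> pd.Series:
    """Flag genes expressed: >= ``min_consecutive`` consecutive samples above
    the matrix-wide ``background_quantile`` threshold."""
    thr = np.quantile(tc.matrix, background_quantile)
    above = tc.matrix > thr
    runs = above
    for s in range(1, min_consecutive):
        runs = runs[:, :-1] & above[:, s:]
    flags = runs.any(axis=1)
    flags = pd.Series(flags, index=list(tc.gene_ids), name="expressed")
    if tc.excluded:
        flags[flags.index.isin(tc.excluded)] = False
    return flags


@dataclass(frozen=True)
class CyclingCallSet:
    """Per-gene expressed/rhythmic calls for one condition.

    ``calls`` is indexed by gene with columns ``expressed``, ``rhythmic``,
    ``shape``, ``phase`` (hours in [0, 24), NaN unless rhythmic), ``R`` and
    ``amplitude`` (max - min of the log2 profile).
    """

    condition: str
    calls: pd.DataFrame
    r_min: float = DEFAULT_R_MIN

    @property
    def total(self) -> int:
        return len(self.calls)

    def rhythmic_genes(self) -> frozenset:
        return frozenset(self.calls.index[self.calls["rhythmic"]])

    def expressed_genes(self) -> frozenset:
        return frozenset(self.calls.index[self.calls["expressed"]])

    def phase_of(self) -> pd.Series:
        """Phase (hours) for rhythmic genes only."""
        return self.calls.loc[self.calls["rhythmic"], "phase"]

    def summary(self) -> dict:
        return summarize_calls(self)


def detect_cycling(
    tc: TimeCourse,
    lib: ModelLibrary,
    r_min: float = DEFAULT_R_MIN,
    expressed: pd.Series | None = None,
    log2_input: bool = False,
) -> CyclingCallSet:
    """Score every expressed gene against the model library.

    Analysis is on ``log2(intensity + 1)`` unless the matrix is already on
    the log scale (``log2_input``).  The best template is the correlation
    argmax; ties resolve to the earlier phase, then shape order.  Constant
    profiles have undefined correlation and are never rhythmic.
    """
    if expressed is None:
        expressed = call_expressed(tc)
    expressed = expressed.reindex(list(tc.gene_ids), fill_value=False)

    x = tc.matrix if log2_input else np.log2(tc.matrix + 1.0)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    constant = sd[:, 0] < 1e-12
    if constant.any():
        logger.info(
            "%s: %d constant profile(s) have undefined correlation; not rhythmic",
            tc.condition, int(constant.sum()),
        )
    z = np.where(constant[:, None], 0.0, (x - mean) / np.where(sd == 0, 1.0, sd))
    corr = z @ lib.templates.T / x.shape[1]

    best_idx = corr.argmax(axis=1)  # first max -> earlier phase, then shape order
    best_r = corr[np.arange(len(best_idx)), best_idx]
    best_r = np.where(constant, np.nan, best_r)

    rhythmic = expressed.to_numpy() & ~constant & (best_r >= r_min)
    shape = np.array([lib.meta[i][0] for i in best_idx], dtype=object)
    phase = np.array([lib.meta[i][1] for i in best_idx])
    calls = pd.DataFrame(
        {
            "expressed": expressed.to_numpy(),
            "rhythmic": rhythmic,
            "shape": np.where(rhythmic, shape, None),
            "phase": np.where(rhythmic, phase, np.nan),
            "R": best_r,
            "amplitude": x.max(axis=1) - x.min(axis=1),
        },
        index=list(tc.gene_ids),
    )
    return CyclingCallSet(condition=tc.condition, calls=calls, r_min=r_min)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def summarize_counts(total: int, not_expressed: int, rhythmic: int) -> dict:
    """Summary row from raw counts, with the survey's mixed denominators:
    not-expressed % and not-rhythmic % of total, rhythmic % of expressed."""
    expressed = total - not_expressed
    not_rhythmic = expressed - rhythmic
    if not_rhythmic < 0:
        raise ValueError("rhythmic count exceeds expressed count")
    return {
        "total": total,
        "not_expressed": not_expressed,
        "not_rhythmic": not_rhythmic,
        "rhythmic": rhythmic,
        "not_expressed_pct": _round_half_up(100.0 * not_expressed / total),
        "not_rhythmic_pct": _round_half_up(100.0 * not_rhythmic / total),
        "rhythmic_pct": _round_half_up(100.0 * rhythmic / expressed)
        if expressed
        else 0,
    }


def summarize_calls(ccs: CyclingCallSet) -> dict:
    c = ccs.calls
    return summarize_counts(
        total=len(c),
        not_expressed=int((~c["expressed"]).sum()),
        rhythmic=int(c["rhythmic"].sum()),
    )


def phase_lists(ccs: CyclingCallSet, bins: int = 24) -> dict:
    """Split a condition's rhythmic genes into hourly phase bins.

    With ``bins = 24`` each integer hour is one list.  With ``bins = 23``
    the two adjacent hourly bins with the smallest combined membership are
    merged (the merged list keeps the lower hour's label), mirroring
    analyses that report 23 phase lists per time course.
    """
    if bins not in (24, 23):
        raise ValueError("bins must be 24 or 23")
    phases = ccs.phase_of()
    hour = np.floor(phases.to_numpy()).astype(int) % 24
    lists: dict[int, list] = {h: [] for h in range(24)}
    for gene, h in zip(phases.index, hour):
        lists[h].append(gene)
    if bins == 24:
        return {h: tuple(lists[h]) for h in range(24)}
    counts = np.array([len(lists[h]) for h in range(24)])
    pair_sums = counts[:-1] + counts[1:]
    i = int(pair_sums.argmin())  # merge the sparsest adjacent pair (ties: earliest)
    merged: dict[int, tuple] = {}
    for h in range(24):
        if h == i:
            merged[h] = tuple(lists[h] + lists[h + 1])
        elif h == i + 1:
            continue
        else:
            merged[h] = tuple(lists[h])
    return merged
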