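"""Circular phase-shift analyses between developmental conditions.

Two complementary views of how the time of peak expression moves across a
developmental series:

* **baseline analysis** — every condition compared to a fixed anchor (the
  first developmental stage), revealing cumulative seasonal drift;
* **incremental analysis** — each consecutive (proximal) pair of
  conditions, revealing when during development the drift happens.

Shifts are circular on a 24 h clock.  The primary statistic is the forward
shift ``(phase_target - phase_ref) mod 24`` in ``[0, 24)``; the signed shift
in ``[-12, 12)`` is auxiliary.  Only genes rhythmic in both conditions of a
pair enter a table — phase is undefined otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cycling_detection import CyclingCallSet

__all__ = [
    "PhaseShiftTable",
    "circular_shift",
    "baseline_analysis",
    "incremental_analysis",
    "select_shift_window",
]


def circular_shift(p_ref, p_target):
    """Forward (``[0,24)``) and signed (``[-12,12)``) circular shift.

    Accepts scalars or arrays; phases are hours mod 24.
    """
    forward = np.mod(np.asarray(p_target, dtype=float) - np.asarray(p_ref, dtype=float), 24.0)
    signed = np.where(forward >= 12.0, forward - 24.0, forward)
    if np.isscalar(p_ref) and np.isscalar(p_target):
        return float(forward), float(signed)
    return forward, signed


@dataclass(frozen=True)
class PhaseShiftTable:
    """Per-gene circular phase differences for one (reference, target) pair."""

    reference: str
    target: str
    table: pd.DataFrame  # index gene; columns forward, signed

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> tuple:
        return tuple(self.table.index)

    def histogram(self, bins: int = 24) -> np.ndarray:
        """Counts of genes per 1 h forward-shift bin (24 bins by default)."""
        hours = np.floor(self.table["forward"].to_numpy()).astype(int) % 24
        return np.bincount(hours, minlength=bins)[:bins]

    def modal_shift(self) -> int:
        """The most populated forward-shift hour bin."""
        return int(self.histogram().argmax())

    def same_phase_fraction(self, tolerance: float = 0.0) -> float:
        """Fraction of genes keeping their phase (same 1 h bin by default;
        a circular tolerance in hours can relax the match)."""
        if len(self.table) == 0:
            return float("nan")
        if tolerance <= 0:
            hours = np.floor(self.table["forward"].to_numpy()).astype(int) % 24
            return float(np.mean(hours == 0))
        signed = self.table["signed"].to_numpy()
        return float(np.mean(np.abs(signed) <= tolerance))


def _shift_table(ref: CyclingCallSet, target: CyclingCallSet) -> PhaseShiftTable:
    common = sorted(ref.rhythmic_genes() & target.rhythmic_genes())
    p_ref = ref.calls.loc[common, "phase"].to_numpy(dtype=float)
    p_tgt = target.calls.loc[common, "phase"].to_numpy(dtype=float)
    forward, signed = circular_shift(p_ref, p_tgt)
    table = pd.DataFrame({"forward": forward, "signed": signed}, index=common)
    return PhaseShiftTable(reference=ref.condition, target=target.condition, table=table)


def baseline_analysis(
    callsets: Sequence[CyclingCallSet], anchor: str
) -> list:
    """One shift table per non-anchor condition versus the anchor condition."""
    by_name = {c.condition: c for c in callsets}
    if anchor not in by_name:
        raise ValueError(f"anchor condition {anchor!r} not among callsets")
    if len(callsets) < 2:
        raise ValueError("need at least two conditions")
    ref = by_name[anchor]
    return [_shift_table(ref, c) for c in callsets if c.condition != anchor]


def incremental_analysis(callsets: Sequence[CyclingCallSet]) -> list:
    """Shift tables for each consecutive pair in developmental order."""
    return [_shift_table(a, b) for a, b in zip(callsets[:-1], callsets[1:])]


def select_shift_window(table: PhaseShiftTable, lo: float, hi: float) -> tuple:
    """Genes whose forward shift lies in ``[lo, hi]`` (inclusive).

    The window is in forward-shift space, so asymmetric late-shift classes
    (e.g. 6-19 h) are expressible; the result feeds GO enrichment.
    """
    if not lo < hi:
        raise ValueError("window requires lo < hi in forward-shift space")
    fw = table.table["forward"]
    return tuple(fw.index[(fw >= lo) & (fw <= hi)])
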