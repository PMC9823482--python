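"""Phase-binned GO-term overrepresentation per condition.

Each (condition, phase bin) rhythmic-gene list is tested for GO-term
overrepresentation against that condition's expressed genes (the genes that
could have been phased), by an upper-tail hypergeometric test per annotated
term with BH-FDR across the tested terms; a term is significant at
q < 0.05.  The map is used as-is (no ancestor propagation), matching
annotation-derived term extraction.  Summaries count, per condition, the
terms significant at >= 1 time of day, and per term its "occurrences per
day" (how many bins it is significant in) — terms significant at many hours
flag broadly regulated processes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cycling_detection import CyclingCallSet, phase_lists
from .stats import bh_qvalues, hypergeom_pvalue
from .timecourse_io import GeneGOMap

logger = logging.getLogger(__name__)

__all__ = [
    "GOTODResult",
    "enrich_go",
    "run_go_tod",
    "overlap_analysis",
    "venn3_counts",
]

_COLS = ["term", "study_count", "study_size", "pop_count", "pop_size",
         "p", "q", "significant"]


def enrich_go(
    gene_list: Sequence[str],
    universe: Sequence[str],
    gomap: GeneGOMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term hypergeometric overrepresentation of ``gene_list`` within
    ``universe``, BH-adjusted across the tested terms."""
    universe = set(universe)
    study = set(gene_list) & universe
    if len(study) < len(set(gene_list)):
        logger.warning("%d study gene(s) outside the universe; dropped",
                       len(set(gene_list)) - len(study))
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in universe:
        for term in gomap.terms_for(gene):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1
    if not term_pop:
        return pd.DataFrame(columns=_COLS)
    terms = sorted(term_pop)
    pop = np.array([term_pop[t] for t in terms])
    stu = np.array([term_study.get(t, 0) for t in terms])
    p = hypergeom_pvalue(stu, len(study), pop, len(universe))
    q = bh_qvalues(p)
    return pd.DataFrame(
        {
            "term": terms,
            "study_count": stu,
            "study_size": len(study),
            "pop_count": pop,
            "pop_size": len(universe),
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    )


@dataclass(frozen=True)
class GOTODResult:
    """GO enrichment over all (condition x phase bin) lists, plus marginals.

    ``results`` has one row per (condition, phase_bin, term);
    ``significant_terms`` maps condition -> terms significant in >= 1 bin;
    ``occurrences`` is a term x condition frame counting significant bins
    per day.
    """

    results: pd.DataFrame
    alpha: float

    @property
    def significant_terms(self) -> dict:
        out: dict[str, frozenset] = {}
        for cond in pd.unique(self.results["condition"]) if not self.results.empty else []:
            sub = self.results[(self.results["condition"] == cond)
                               & self.results["significant"]]
            out[cond] = frozenset(sub["term"])
        return out

    @property
    def occurrences(self) -> pd.DataFrame:
        """Occurrences per day: significant bins per (term, condition)."""
        if self.results.empty:
            return pd.DataFrame()
        sig = self.results[self.results["significant"]]
        return (
            sig.groupby(["term", "condition"]).size().unstack(fill_value=0)
        )

    def summary_counts(self) -> dict:
        """Per condition, the number of terms significant at >= 1 TOD."""
        return {c: len(ts) for c, ts in self.significant_terms.items()}

    def term_profile(self, term: str, cap: float = 10.0) -> pd.DataFrame:
        """-log10(q) per (condition, phase bin) where significant, else 0."""
        df = self.results
        conds = list(pd.unique(df["condition"]))
        bins = sorted(pd.unique(df["phase_bin"]))
        profile = pd.DataFrame(0.0, index=conds, columns=bins)
        hits = df[(df["term"] == term) & df["significant"]]
        for _, row in hits.iterrows():
            q = max(float(row["q"]), 1e-300)
            profile.loc[row["condition"], row["phase_bin"]] = min(-np.log10(q), cap)
        return profile


def run_go_tod(
    callsets: Sequence[CyclingCallSet],
    gomap: GeneGOMap,
    alpha: float = 0.05,
    bins: int = 24,
    universe: str = "expressed",
) -> GOTODResult:
    """GO enrichment for every condition x phase-bin rhythmic-gene list.

    ``universe`` is ``"expressed"`` (that condition's expressed genes,
    default) or ``"all"`` (every gene on the platform).
    """
    if universe not in ("expressed", "all"):
        raise ValueError("universe must be 'expressed' or 'all'")
    frames = []
    for ccs in callsets:
        uni = (
            sorted(ccs.expressed_genes())
            if universe == "expressed"
            else list(ccs.calls.index)
        )
        for label, genes in phase_lists(ccs, bins=bins).items():
            if not genes:
                logger.info("empty phase list %s bin %s: skipped", ccs.condition, label)
                continue
            df = enrich_go(genes, uni, gomap, alpha=alpha)
            if df.empty:
                continue
            df.insert(0, "condition", ccs.condition)
            df.insert(1, "phase_bin", label)
            frames.append(df)
    results = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["condition", "phase_bin", *_COLS])
    )
    return GOTODResult(results=results, alpha=alpha)


def overlap_analysis(
    term_sets: Mapping[str, frozenset] | GOTODResult,
    order: Sequence[str] | None = None,
    window: int = 2,
    phase_groups: Mapping[str, Sequence[str]] | None = None,
) -> dict:
    """Cross-condition overlaps of significant term sets.

    Returns ``shared_all`` (intersection across every condition),
    ``sliding`` (width-``window`` intersections in developmental order) and,
    when ``phase_groups`` maps group names to condition lists, a 3-way
    ``venn`` of the groups' term-set unions.
    """
    if isinstance(term_sets, GOTODResult):
        term_sets = term_sets.significant_terms
    order = list(order) if order is not None else list(term_sets)
    sets = [frozenset(term_sets[c]) for c in order]
    shared_all = frozenset.intersection(*sets) if sets else frozenset()
    sliding = [
        (tuple(order[i : i + window]),
         frozenset.intersection(*sets[i : i + window]))
        for i in range(len(order) - window + 1)
    ]
    out = {"shared_all": shared_all, "sliding": sliding}
    if phase_groups is not None:
        groups = {
            name: frozenset().union(*(term_sets[c] for c in conds))
            for name, conds in phase_groups.items()
        }
        if len(groups) == 3:
            out["venn"] = venn3_counts(groups)
        out["groups"] = groups
    return out


def venn3_counts(groups: Mapping[str, frozenset]) -> dict:
    """Exact 3-way Venn cell counts keyed by membership pattern '101' etc."""
    if len(groups) != 3:
        raise ValueError("need exactly three sets")
    names = list(groups)
    a, b, c = (frozenset(groups[n]) for n in names)
    cells = {}
    for pattern in ("100", "010", "001", "110", "101", "011", "111"):
        inc = [s for s, bit in zip((a, b, c), pattern) if bit == "1"]
        exc = [s for s, bit in zip((a, b, c), pattern) if bit == "0"]
        cell = frozenset.intersection(*inc)
        for s in exc:
            cell -= s
        cells[pattern] = len(cell)
    cells["names"] = tuple(names)
    return cells
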