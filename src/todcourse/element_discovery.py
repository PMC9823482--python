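"""Promoter 3-8 bp kmer time-of-day overrepresentation and motif clustering.

For each (condition, phase bin) gene list, every DNA word of length 3-8 is
tested for overrepresentation among the list's promoters against the
promoter universe: a hypergeometric upper-tail test on promoter *presence*
(a word counts once per promoter regardless of copy number), with BH-FDR
across the full 87,360-word dictionary within each list.  Words significant
in at least one list are greedily clustered by ungapped sequence similarity
into motifs with a consensus position-frequency matrix, and each word or
motif gets a TOD significance profile (-log10 q across condition x phase
bin) — the classic readout on which the Evening Element lights up at dusk
and the Telobox around midnight.

Counting is forward-strand by default (the canonical diurnal elements are
strand-specific strings); ``both_strands`` unions reverse-complement
presence.  Windows containing N are skipped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cycling_detection import CyclingCallSet, phase_lists
from .stats import bh_qvalues, hypergeom_pvalue
from .timecourse_io import PromoterSet

logger = logging.getLogger(__name__)

__all__ = [
    "KMIN",
    "KMAX",
    "DICTIONARY_SIZE",
    "KmerDictionary",
    "MotifCluster",
    "ElementResult",
    "promoter_kmer_set",
    "build_dictionary",
    "enrich_kmers",
    "schedule_phase_lists",
    "run_element",
    "cluster_kmers",
    "tod_profile",
]

KMIN, KMAX = 3, 8
#: analytic dictionary size: sum of 4^k for k = 3..8
DICTIONARY_SIZE = sum(4**k for k in range(KMIN, KMAX + 1))

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def promoter_kmer_set(seq: str, both_strands: bool = False) -> set:
    """All distinct 3-8 bp words present in one promoter (N windows skipped)."""
    seq = seq.upper()
    out: set = set()
    n = len(seq)
    for k in range(KMIN, KMAX + 1):
        for i in range(n - k + 1):
            w = seq[i : i + k]
            if "N" not in w:
                out.add(w)
    if both_strands:
        out |= {_revcomp(w) for w in out}
    return out


@dataclass(frozen=True)
class KmerDictionary:
    """Background promoter-presence counts over the promoter universe."""

    counts: Mapping[str, int]
    universe_size: int
    universe_genes: tuple
    both_strands: bool = False

    def background(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)


def build_dictionary(
    promoters: PromoterSet, both_strands: bool = False
) -> KmerDictionary:
    """Count, for every 3-8 bp word, how many promoters contain it."""
    if len(promoters) == 0:
        raise ValueError("promoter set is empty")
    counts: Counter = Counter()
    for gene in promoters:
        counts.update(promoter_kmer_set(promoters[gene], both_strands))
    return KmerDictionary(
        counts=dict(counts),
        universe_size=len(promoters),
        universe_genes=promoters.genes,
        both_strands=both_strands,
    )


def enrich_kmers(
    dictionary: KmerDictionary,
    gene_list: Sequence[str],
    promoters: PromoterSet,
    alpha: float = 0.05,
    condition: str | None = None,
    phase_bin: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of every kmer in one gene list.

    BH adjustment runs within this list across the full dictionary (family
    size 87,360); kmers absent from the list have p = 1 and are not
    materialized.  Returns a frame with columns kmer, foreground,
    list_size, background, universe, p, q, significant.
    """
    genes = [g for g in gene_list if g in promoters]
    if len(genes) < len(gene_list):
        logger.warning("%d gene(s) in list without promoters; dropped",
                       len(gene_list) - len(genes))
    cols = ["kmer", "foreground", "list_size", "background", "universe",
            "p", "q", "significant"]
    if not genes:
        df = pd.DataFrame(columns=cols)
    else:
        fg_counts: Counter = Counter()
        for g in genes:
            fg_counts.update(promoter_kmer_set(promoters[g], dictionary.both_strands))
        kmers = sorted(fg_counts)
        fg = np.array([fg_counts[k] for k in kmers])
        bg = np.array([dictionary.background(k) for k in kmers])
        p = hypergeom_pvalue(fg, len(genes), bg, dictionary.universe_size)
        q = bh_qvalues(p, m=DICTIONARY_SIZE)
        df = pd.DataFrame(
            {
                "kmer": kmers,
                "foreground": fg,
                "list_size": len(genes),
                "background": bg,
                "universe": dictionary.universe_size,
                "p": p,
                "q": q,
                "significant": q < alpha,
            }
        )
    if condition is not None:
        df.insert(0, "condition", condition)
    if phase_bin is not None:
        df.insert(1 if condition is not None else 0, "phase_bin", phase_bin)
    return df


def schedule_phase_lists(
    callsets: Sequence[CyclingCallSet], bins: int = 24
) -> list:
    """All (condition, phase-bin label, gene tuple) lists for enrichment.

    With 11 conditions and the 23-bin option this schedules 253 lists.
    Empty bins are scheduled here and skipped (with a log entry) at
    enrichment time.
    """
    out = []
    for ccs in callsets:
        for label, genes in phase_lists(ccs, bins=bins).items():
            out.append((ccs.condition, label, genes))
    return out


@dataclass(frozen=True)
class ElementResult:
    """Per-list kmer enrichment over all (condition x phase bin) lists."""

    results: pd.DataFrame  # columns: condition, phase_bin, kmer, ..., q, significant
    n_lists: int
    alpha: float

    def significant_kmers(self) -> frozenset:
        """Kmers significant (q < alpha) in at least one list."""
        if self.results.empty:
            return frozenset()
        return frozenset(self.results.loc[self.results["significant"], "kmer"])

    def conditions(self) -> tuple:
        if self.results.empty:
            return ()
        return tuple(pd.unique(self.results["condition"]))


def run_element(
    callsets: Sequence[CyclingCallSet],
    promoters: PromoterSet,
    alpha: float = 0.05,
    bins: int = 24,
    both_strands: bool = False,
) -> ElementResult:
    """ELEMENT-style analysis across every condition x phase-bin list."""
    dictionary = build_dictionary(promoters, both_strands=both_strands)
    schedule = schedule_phase_lists(callsets, bins=bins)
    frames = []
    for condition, label, genes in schedule:
        if not genes:
            logger.info("empty phase list %s bin %s: skipped", condition, label)
            continue
        frames.append(
            enrich_kmers(dictionary, genes, promoters, alpha=alpha,
                         condition=condition, phase_bin=label)
        )
    results = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["condition", "phase_bin", "kmer", "foreground", "list_size",
                     "background", "universe", "p", "q", "significant"]
        )
    )
    return ElementResult(results=results, n_lists=len(schedule), alpha=alpha)


def _best_alignment(a: str, b: str, min_overlap: int = 3):
    """Best ungapped offset of ``b`` relative to ``a``: (matches, offset).

    Offset o aligns b[i] with a[o + i].  Ties go to the smallest offset.
    """
    best = (-1, 0)
    for off in range(-(len(b) - 1), len(a)):
        start = max(0, off)
        end = min(len(a), off + len(b))
        if end - start < min_overlap:
            continue
        matches = sum(1 for i in range(start, end) if a[i] == b[i - off])
        if matches > best[0]:
            best = (matches, off)
    return best


def _linked(a: str, b: str, min_overlap: int = 3) -> bool:
    """Two kmers link iff some ungapped alignment with overlap >= 3 matches
    at least min(len) - 1 positions."""
    need = min(len(a), len(b)) - 1
    matches, _ = _best_alignment(a, b, min_overlap)
    return matches >= need


@dataclass(frozen=True)
class MotifCluster:
    """A similarity cluster of significant kmers in a common alignment frame.

    ``members`` maps each kmer to its offset in the frame; ``pfm`` is the
    position-frequency matrix (rows A, C, G, T) whose column sums equal the
    number of members covering that position.
    """

    members: Mapping[str, int]
    pfm: pd.DataFrame

    def __len__(self) -> int:
        return len(self.members)

    @property
    def kmers(self) -> tuple:
        return tuple(self.members)

    def consensus(self) -> str:
        return "".join(self.pfm.idxmax(axis=0))


def _build_cluster(members: Sequence[str], min_overlap: int = 3) -> MotifCluster:
    anchor = sorted(members, key=lambda k: (-len(k), k))[0]
    offsets = {}
    for k in members:
        _, off = _best_alignment(anchor, k, min_overlap) if k != anchor else (0, 0)
        offsets[k] = off
    lo = min(offsets.values())
    length = max(off + len(k) for k, off in offsets.items()) - lo
    counts = np.zeros((4, length), dtype=int)
    rows = {b: i for i, b in enumerate("ACGT")}
    for k, off in offsets.items():
        for i, base in enumerate(k):
            counts[rows[base], off - lo + i] += 1
    pfm = pd.DataFrame(counts, index=list("ACGT"), columns=range(length))
    return MotifCluster(members={k: off - lo for k, off in offsets.items()}, pfm=pfm)


def cluster_kmers(kmers: Iterable[str], min_overlap: int = 3) -> list:
    """Greedy single-linkage clustering of significant kmers into motifs."""
    kmers = sorted(set(kmers))
    if not kmers:
        return []
    parent = list(range(len(kmers)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(kmers)):
        for j in range(i + 1, len(kmers)):
            if _linked(kmers[i], kmers[j], min_overlap):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list] = {}
    for i, k in enumerate(kmers):
        groups.setdefault(find(i), []).append(k)
    clusters = [_build_cluster(g, min_overlap) for g in groups.values()]
    clusters.sort(key=lambda c: (-len(c), c.kmers[0]))
    return clusters


def tod_profile(
    result: ElementResult,
    motif_or_kmer,
    cap: float = 10.0,
    conditions: Sequence[str] | None = None,
    bins: Sequence[int] | None = None,
) -> pd.DataFrame:
    """TOD significance profile: -log10(q) per (condition, phase bin) cell,
    capped at ``cap``; cells where the kmer is not significant are 0.  For a
    cluster, each cell takes the best (minimum-q) member.
    """
    if isinstance(motif_or_kmer, MotifCluster):
        kmers = set(motif_or_kmer.kmers)
    elif isinstance(motif_or_kmer, str):
        kmers = {motif_or_kmer}
    else:
        kmers = set(motif_or_kmer)
    df = result.results
    if conditions is None:
        conditions = list(result.conditions())
    if bins is None:
        bins = sorted(pd.unique(df["phase_bin"])) if not df.empty else []
    profile = pd.DataFrame(0.0, index=list(conditions), columns=list(bins))
    hits = df[df["kmer"].isin(kmers) & df["significant"]]
    for (cond, pbin), grp in hits.groupby(["condition", "phase_bin"]):
        if cond in profile.index and pbin in profile.columns:
            q = max(float(grp["q"].min()), 1e-300)
            profile.loc[cond, pbin] = min(-np.log10(q), cap)
    return profile
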