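"""Readers, writers and core containers for every format the pipeline touches.

Formats are deliberately plain text: tab-delimited expression matrices (genes
as rows, one column per ZT sample), FASTA promoters, and two-column
gene<TAB>GO:ID maps (GAF also accepted).  All readers are total on valid
inputs and fail loudly, naming the offending line, on invalid ones.

ZT convention
-------------
Samples are labelled in Zeitgeber-time "label space" starting at ZT6 by
default (sampling began 6 h after the nominal ZT0 set point; the collection
clock time defining ZT0 is metadata, not arithmetic).  A configurable
``zt_label_offset`` makes the alternative convention (first sample = ZT0)
reproducible; all phases downstream are reported mod 24 in label space.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "TimeCourse",
    "PromoterSet",
    "GeneGOMap",
    "read_expression_table",
    "write_expression_table",
    "read_fasta_promoters",
    "write_fasta_promoters",
    "read_gene_go",
    "write_gene_go",
]

GO_TERM_RE = re.compile(r"^GO:\d{7}$")
_DNA = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated the expected format; the message names the offender."""


@dataclass(frozen=True)
class TimeCourse:
    """One condition's gene x timepoint intensity matrix plus sampling metadata.

    ``matrix`` holds linear-scale intensities (one row per gene, one column
    per ZT sample).  ``excluded`` lists genes whose profiles had too many
    missing values to be trusted by rhythmicity calling; they are carried in
    the matrix (interpolated) but gated out as "not expressed" downstream.
    """

    condition: str
    gene_ids: tuple
    zt: np.ndarray
    matrix: np.ndarray
    tissue: str | None = None
    day_of_season: int | None = None
    zt_label_offset: float = 6.0
    excluded: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        zt = np.asarray(self.zt, dtype=float)
        matrix = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "zt", zt)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if matrix.shape != (len(self.gene_ids), len(zt)):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(zt)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dupes}")
        if len(zt) >= 2 and not np.all(np.diff(zt) > 0):
            raise ValueError("zt grid must be strictly increasing")
        if np.any(matrix < 0):
            raise ValueError("linear-scale intensities must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"ZT{z:g}" for z in self.zt]
        return pd.DataFrame(self.matrix, index=list(self.gene_ids), columns=cols)

    def with_matrix(self, matrix: np.ndarray) -> "TimeCourse":
        return replace(self, matrix=np.asarray(matrix, dtype=float))


def _parse_zt_label(label: str) -> float:
    m = re.fullmatch(r"(?:ZT)?\s*([0-9]+(?:\.[0-9]+)?)", label.strip(), re.IGNORECASE)
    if not m:
        raise FormatError(f"cannot parse ZT hour from column header {label!r}")
    return float(m.group(1))


def read_expression_table(
    path,
    condition: str | None = None,
    tissue: str | None = None,
    day_of_season: int | None = None,
    zt_label_offset: float = 6.0,
    max_interpolated: int = 1,
) -> TimeCourse:
    """Read a tab-delimited genes x ZT-samples intensity table.

    A single missing cell per gene is linearly interpolated from flanking
    timepoints; genes with more missing cells are retained (interpolated)
    but flagged in ``TimeCourse.excluded`` so rhythmicity calling counts
    them as not expressed.  Ragged rows, duplicate gene ids and non-numeric
    cells raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    if raw.empty or raw.shape[1] == 0:
        raise FormatError(f"{path.name}: no data rows/columns")
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise FormatError(f"{path.name}: duplicate gene ids {dupes}")
    zt = np.array([_parse_zt_label(c) for c in raw.columns])

    values = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    stripped = raw.apply(lambda c: c.astype("string").str.strip())
    bad = values.isna() & stripped.notna() & (stripped != "")
    # a cell is "missing" if empty/NA; "malformed" if present but non-numeric
    if bad.any().any():
        genes = values.index[bad.any(axis=1)]
        lines = [raw.index.get_loc(g) + 2 for g in genes]  # +1 header, +1 1-based
        raise FormatError(
            f"{path.name}: non-numeric cells in gene(s) {list(genes)} "
            f"(line(s) {lines})"
        )

    matrix = values.to_numpy(dtype=float)
    excluded = set()
    n_missing = np.isnan(matrix).sum(axis=1)
    for i in np.flatnonzero(n_missing):
        gene = raw.index[i]
        row = matrix[i]
        ok = ~np.isnan(row)
        if ok.sum() == 0:
            raise FormatError(f"{path.name}: gene {gene!r} has no numeric values")
        matrix[i] = np.interp(zt, zt[ok], row[ok])
        if n_missing[i] > max_interpolated:
            excluded.add(gene)
            logger.warning(
                "%s: gene %s has %d missing values; excluded from rhythmicity calling",
                path.name, gene, int(n_missing[i]),
            )
        else:
            logger.info("%s: interpolated %d missing value(s) for gene %s",
                        path.name, int(n_missing[i]), gene)

    return TimeCourse(
        condition=condition or path.stem,
        gene_ids=tuple(raw.index),
        zt=zt,
        matrix=matrix,
        tissue=tissue,
        day_of_season=day_of_season,
        zt_label_offset=zt_label_offset,
        excluded=frozenset(excluded),
    )


def write_expression_table(tc: TimeCourse, path) -> None:
    tc.to_frame().to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


@dataclass(frozen=True)
class PromoterSet:
    """Gene -> uppercase DNA promoter string (fixed length, default 500 bp)."""

    sequences: Mapping[str, str]

    def __post_init__(self):
        seqs = {}
        for gene, seq in self.sequences.items():
            seq = str(seq).upper()
            extra = set(seq) - _DNA
            if extra:
                raise FormatError(
                    f"promoter {gene!r}: non-DNA characters {sorted(extra)}"
                )
            seqs[str(gene)] = seq
        object.__setattr__(self, "sequences", seqs)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, gene) -> bool:
        return gene in self.sequences

    def __getitem__(self, gene) -> str:
        return self.sequences[gene]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    @property
    def genes(self) -> tuple:
        return tuple(self.sequences)

    def lengths(self) -> set:
        return {len(s) for s in self.sequences.values()}


def read_fasta_promoters(path, expected_length: int | None = None) -> PromoterSet:
    """Read promoters from FASTA; lowercase is coerced to uppercase.

    With ``expected_length`` set (strict mode), any record of a different
    length raises :class:`FormatError`.
    """
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate promoter record {rec.id!r}")
        seq = str(rec.seq).upper()
        if expected_length is not None and len(seq) != expected_length:
            raise FormatError(
                f"promoter {rec.id!r} has length {len(seq)}, expected {expected_length}"
            )
        records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return PromoterSet(records)


def write_fasta_promoters(promoters: PromoterSet, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in promoters.sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True)
class GeneGOMap:
    """Gene -> set of GO term ids; the term universe derives from the map."""

    annotations: Mapping[str, frozenset]

    def __post_init__(self):
        ann = {}
        for gene, terms in self.annotations.items():
            terms = frozenset(terms)
            for t in terms:
                if not GO_TERM_RE.match(t):
                    raise FormatError(f"malformed GO id {t!r} for gene {gene!r}")
            ann[str(gene)] = terms
        object.__setattr__(self, "annotations", ann)

    def __len__(self) -> int:
        return len(self.annotations)

    def __contains__(self, gene) -> bool:
        return gene in self.annotations

    def terms_for(self, gene) -> frozenset:
        return self.annotations.get(gene, frozenset())

    @property
    def genes(self) -> tuple:
        return tuple(self.annotations)

    @property
    def term_universe(self) -> frozenset:
        out = set()
        for terms in self.annotations.values():
            out.update(terms)
        return frozenset(out)

    def genes_with_term(self, term: str) -> frozenset:
        return frozenset(g for g, ts in self.annotations.items() if term in ts)


def read_gene_go(path, known_genes: Iterable[str] | None = None) -> GeneGOMap:
    """Read a gene->GO map from two-column TSV or GAF (columns 2 and 5).

    Genes absent from ``known_genes`` (e.g. the expression data) are retained
    and flagged in the log, never dropped.
    """
    path = Path(path)
    ann: dict[str, set] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                gene, term = parts
            elif len(parts) >= 5:  # GAF: DB, DB Object ID, Symbol, Qualifier, GO ID
                gene, term = parts[1], parts[4]
            else:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 2-column TSV or GAF row"
                )
            term = term.strip()
            if not GO_TERM_RE.match(term):
                raise FormatError(f"{path.name}:{lineno}: malformed GO id {term!r}")
            ann.setdefault(gene.strip(), set()).add(term)
            n_lines += 1
    if n_lines == 0:
        raise FormatError(f"{path.name}: empty gene->GO map")
    if known_genes is not None:
        unknown = sorted(set(ann) - set(known_genes))
        if unknown:
            logger.warning(
                "%s: %d annotated gene(s) absent from expression data (retained): %s%s",
                path.name, len(unknown), ", ".join(unknown[:5]),
                "..." if len(unknown) > 5 else "",
            )
    return GeneGOMap({g: frozenset(ts) for g, ts in ann.items()})


def write_gene_go(gomap: GeneGOMap, path) -> None:
    with open(path, "w") as fh:
        for gene in gomap.genes:
            for term in sorted(gomap.terms_for(gene)):
                fh.write(f"{gene}\t{term}\n")
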