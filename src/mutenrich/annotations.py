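"""Gene-to-term annotations: GAF parsing and propagated annotation index.

The index applies the true-path rule: a gene annotated to a term is
implicitly annotated to every ancestor of that term, so per-term gene
counts are monotone non-decreasing toward each namespace root.  The
index is the source of ``f(t)`` for information content and of the
genome-wide per-term counts used by the profiling analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

from .ontology import OntologyGraph

__all__ = [
    "GeneAnnotation",
    "GafParseReport",
    "AnnotationIndex",
    "parse_gaf",
    "build_index",
    "genome_term_count",
]

logger = logging.getLogger(__name__)

# GAF 2.x column indices (0-based) for the fields we consume
_COL_SYMBOL = 2
_COL_QUALIFIER = 3
_COL_TERM = 4
_COL_EVIDENCE = 6
_COL_ASPECT = 8
_MIN_COLUMNS = 15  # GAF 2.0 mandates 17 columns; accept >=15 to be tolerant


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene -> term assignment from a GAF row."""

    gene_symbol: str
    term_id: str
    evidence_code: str
    aspect: str


@dataclass
class GafParseReport:
    """Bookkeeping from one GAF parse (rows seen / kept / skipped)."""

    n_rows: int = 0
    n_kept: int = 0
    n_not_qualified: int = 0
    n_malformed: int = 0
    n_evidence_filtered: int = 0


def parse_gaf(
    source: str | IO[str],
    evidence_filter: Iterable[str] | None = None,
) -> tuple[list[GeneAnnotation], GafParseReport]:
    """Read GAF 2.x annotation rows.

    Comment lines start with ``!``.  Rows carrying a ``NOT`` qualifier are
    excluded (they assert the absence of a function).  By default every
    evidence code is kept — including IEA (inferred from electronic
    annotation); pass ``evidence_filter`` to restrict.  Rows with too few
    columns are skipped with a warning and counted in the report.
    """
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    allowed = frozenset(evidence_filter) if evidence_filter is not None else None
    records: list[GeneAnnotation] = []
    report = GafParseReport()
    try:
        for line in source:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            report.n_rows += 1
            cols = line.split("\t")
            if len(cols) < _MIN_COLUMNS:
                report.n_malformed += 1
                logger.warning("skipping GAF row with %d columns: %r", len(cols), line[:80])
                continue
            qualifier = cols[_COL_QUALIFIER]
            if "NOT" in qualifier.split("|"):
                report.n_not_qualified += 1
                continue
            evidence = cols[_COL_EVIDENCE]
            if allowed is not None and evidence not in allowed:
                report.n_evidence_filtered += 1
                continue
            symbol = cols[_COL_SYMBOL]
            term = cols[_COL_TERM]
            if not symbol or not term:
                report.n_malformed += 1
                logger.warning("skipping GAF row with empty symbol/term: %r", line[:80])
                continue
            records.append(GeneAnnotation(symbol, term, evidence, cols[_COL_ASPECT]))
            report.n_kept += 1
    finally:
        if close:
            source.close()
    return records, report


@dataclass
class AnnotationIndex:
    """Bidirectional gene <-> term map after true-path propagation.

    ``gene_to_terms`` and ``term_to_genes`` are exact inverses;
    ``direct_term_to_genes`` retains the pre-propagation assignments.
    """

    gene_to_terms: dict[str, frozenset[str]]
    term_to_genes: dict[str, frozenset[str]]
    direct_term_to_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    n_skipped_terms: int = 0

    @property
    def universe(self) -> frozenset[str]:
        """All annotated genes."""
        return frozenset(self.gene_to_terms)

    def terms_for_gene(self, gene: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene, frozenset())

    def genes_for_term(self, term_id: str) -> frozenset[str]:
        return self.term_to_genes.get(term_id, frozenset())

    def genome_term_count(self, term_id: str) -> int:
        """Number of distinct genes annotated (post-propagation) with a term."""
        return len(self.term_to_genes.get(term_id, ()))

    def direct_term_count(self, term_id: str) -> int:
        return len(self.direct_term_to_genes.get(term_id, ()))

    def write_tsv(self, path) -> None:
        """Export the propagated index as two-column TSV (gene, term_id)."""
        with open(path, "w") as fh:
            fh.write("gene\tterm_id\n")
            for gene in sorted(self.gene_to_terms):
                for term in sorted(self.gene_to_terms[gene]):
                    fh.write(f"{gene}\t{term}\n")


def build_index(annotations: Iterable[GeneAnnotation], graph: OntologyGraph) -> AnnotationIndex:
    """Build the propagated :class:`AnnotationIndex` for an ontology.

    Annotations to unresolvable accessions are skipped with a logged
    count; alt_id accessions resolve to their primary term.  Duplicate
    (gene, term) pairs collapse to one.
    """
    gene_direct: dict[str, set[str]] = {}
    direct_term: dict[str, set[str]] = {}
    skipped = 0
    for ann in annotations:
        try:
            term = graph.resolve(ann.term_id)
        except KeyError:
            skipped += 1
            continue
        gene_direct.setdefault(ann.gene_symbol, set()).add(term)
        direct_term.setdefault(term, set()).add(ann.gene_symbol)
    if skipped:
        logger.warning("skipped %d annotations to unresolvable terms", skipped)

    gene_to_terms: dict[str, frozenset[str]] = {}
    term_to_genes: dict[str, set[str]] = {}
    for gene, direct in gene_direct.items():
        closed: set[str] = set()
        for term in direct:
            closed |= graph.ancestors(term)
        gene_to_terms[gene] = frozenset(closed)
        for term in closed:
            term_to_genes.setdefault(term, set()).add(gene)

    return AnnotationIndex(
        gene_to_terms=gene_to_terms,
        term_to_genes={t: frozenset(g) for t, g in term_to_genes.items()},
        direct_term_to_genes={t: frozenset(g) for t, g in direct_term.items()},
        n_skipped_terms=skipped,
    )


def genome_term_count(index: AnnotationIndex, term_id: str) -> int:
    """Module-level alias for :meth:`AnnotationIndex.genome_term_count`."""
    return index.genome_term_count(term_id)
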