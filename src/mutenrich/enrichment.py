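"""Patient-level singular enrichment analysis.

Classic singular enrichment analysis (SEA) tests each ontology term for
over-representation in one study gene set against one population set
with the hypergeometric upper tail (one-sided Fisher's exact test).
Here both sets are patient-level *multisets* of gene instances — one
instance per (patient, mutated gene) pair — so that every patient
contributes their own mutated-gene set:

* **enrichment profiling** of a patient group: study set = all mutated
  gene instances in the group (size ``n``); population set = the whole
  annotated genome replicated once per patient (size ``N = G x m`` for
  ``m`` patients and ``G`` annotated genes).  A term's population count
  is ``K = m x f(t)`` since all patients share the same genome.
* **differential enrichment** of a subgroup against the whole cohort:
  population set = all mutated gene instances in the cohort, study set
  = the subgroup's mutated instances; a significant term is mutated
  more often in the subgroup than in the cohort at large.

P-values are computed in log space (log-gamma) so that the extreme
tails produced by genome-scale population sets (p ~ 1e-40) do not
underflow.  Multiple testing is handled by Bonferroni correction
(p x number of tested terms); the enriched flag follows the uncorrected
p-value at level alpha, with the corrected value reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .annotations import AnnotationIndex
from .cohort import Cohort
from .ontology import OntologyGraph, TermIC, filter_informative, information_content

__all__ = [
    "TermFrequencyRecord",
    "EnrichmentResult",
    "AnalysisConfig",
    "candidate_terms",
    "profiling_frequencies",
    "differential_frequencies",
    "hypergeometric_tail",
    "log_hypergeometric_tail",
    "correct_pvalues",
    "run_profiling",
    "run_differential",
    "results_to_frame",
    "write_results",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "term_id",
    "name",
    "namespace",
    "p_value",
    "p_bonferroni",
    "k",
    "n",
    "sfreq_pct",
    "K",
    "N",
    "pfreq_pct",
    "ic_normalized",
    "enriched",
]


@dataclass(frozen=True)
class TermFrequencyRecord:
    """The 2x2 table behind one term's test.

    ``study_count`` (k) of ``study_size`` (n) study instances are
    annotated with the term; ``population_count`` (K) of
    ``population_size`` (N) population instances are.
    """

    term_id: str
    study_count: int
    study_size: int
    population_count: int
    population_size: int

    def __post_init__(self):
        k, n, K, N = (
            self.study_count,
            self.study_size,
            self.population_count,
            self.population_size,
        )
        if not (0 <= k <= n):
            raise ValueError(f"{self.term_id}: need 0 <= k <= n, got k={k}, n={n}")
        if not (0 <= K <= N):
            raise ValueError(f"{self.term_id}: need 0 <= K <= N, got K={K}, N={N}")
        if k > K:
            raise ValueError(f"{self.term_id}: study count k={k} exceeds population count K={K}")
        if n > N:
            raise ValueError(f"{self.term_id}: study size n={n} exceeds population size N={N}")


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term with raw and corrected p-values and frequencies."""

    term_id: str
    name: str
    namespace: str
    p_value: float
    p_corrected: float
    study_count: int
    study_size: int
    population_count: int
    population_size: int
    ic_normalized: float
    enriched: bool

    @property
    def sfreq_pct(self) -> float:
        return 100.0 * self.study_count / self.study_size

    @property
    def pfreq_pct(self) -> float:
        return 100.0 * self.population_count / self.population_size


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of an enrichment run.

    ``alpha`` is the significance level on the uncorrected p-value
    (default 0.1); ``ic_threshold`` the strict lower bound on normalised
    information content for a term to be tested (default 0.6);
    Bonferroni's multiplier is the number of tested terms, either
    globally or per namespace; ``cap_corrected_at_one`` clips corrected
    p-values at 1 (disable for report dialects that print e.g. 1.9E+00).
    """

    alpha: float = 0.1
    ic_threshold: float = 0.6
    correction: str = "bonferroni"
    bonferroni_scope: str = "all_tested_terms"
    cap_corrected_at_one: bool = True

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.bonferroni_scope not in ("all_tested_terms", "per_namespace"):
            raise ValueError(f"unknown bonferroni_scope {self.bonferroni_scope!r}")


def candidate_terms(
    index: AnnotationIndex,
    study_genes: Iterable[str],
    informative: frozenset[str] | None = None,
) -> frozenset[str]:
    """Terms annotating at least one study gene, optionally restricted to
    the informative (IC-filtered) set."""
    terms: set[str] = set()
    for gene in study_genes:
        terms |= index.terms_for_gene(gene)
    if not terms:
        warnings.warn("no study gene carries any annotation; candidate set is empty")
    if informative is not None:
        terms &= informative
    return frozenset(terms)


def _annotated_instance_count(multiset: Mapping[str, int], genes_with_term: frozenset[str]) -> int:
    return sum(count for gene, count in multiset.items() if gene in genes_with_term)


def profiling_frequencies(
    cohort: Cohort,
    group: str,
    index: AnnotationIndex,
    genome_size: int,
    terms: Iterable[str] | None = None,
) -> list[TermFrequencyRecord]:
    """Per-term study/population counts for the profiling analysis.

    For a group of ``m`` patients: ``n`` = mutated-gene instances in the
    group, ``N = genome_size x m``, ``k`` = annotated mutated instances,
    ``K = m x f(t)`` (every patient carries the same annotated genome).
    """
    members = cohort.group(group)
    m = len(members)
    if m == 0:
        raise ValueError(f"group {group!r} is empty")
    distinct_panel = len(set(cohort.gene_panel))
    if genome_size < distinct_panel:
        raise ValueError(
            f"genome_size={genome_size} smaller than the {distinct_panel}-gene panel"
        )
    multiset = cohort.mutated_gene_multiset(group)
    n = sum(multiset.values())
    N = genome_size * m
    if terms is None:
        terms = candidate_terms(index, multiset.keys())
    records = []
    for term in sorted(terms):
        genes_with_term = index.genes_for_term(term)
        k = _annotated_instance_count(multiset, genes_with_term)
        K = m * index.genome_term_count(term)
        records.append(TermFrequencyRecord(term, k, n, K, N))
    return records


def differential_frequencies(
    cohort: Cohort,
    subgroup: str,
    index: AnnotationIndex,
    terms: Iterable[str] | None = None,
) -> list[TermFrequencyRecord]:
    """Per-term study/population counts for the differential analysis.

    Population = the cohort-wide mutated multiset (size ``N``), study =
    the subgroup's mutated multiset (size ``n``); ``K`` and ``k`` count
    the annotated instances within each.
    """
    population = cohort.mutated_gene_multiset("all")
    study = cohort.mutated_gene_multiset(subgroup)
    N = sum(population.values())
    n = sum(study.values())
    if n == N:
        warnings.warn(
            "subgroup spans the whole cohort: differential test is degenerate (all p = 1)"
        )
    if terms is None:
        terms = candidate_terms(index, study.keys())
    records = []
    for term in sorted(terms):
        genes_with_term = index.genes_for_term(term)
        k = _annotated_instance_count(study, genes_with_term)
        K = _annotated_instance_count(population, genes_with_term)
        records.append(TermFrequencyRecord(term, k, n, K, N))
    return records


def log_hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """``log P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    Summed in log space from log-gamma terms, so tails down to ~1e-300
    are representable.  ``k <= 0`` gives log(1) = 0.
    """
    if k <= 0:
        return 0.0
    kmax = min(n, K)
    if k > kmax:
        return -np.inf
    j = np.arange(k, kmax + 1)
    log_pmf = (
        gammaln(K + 1)
        - gammaln(j + 1)
        - gammaln(K - j + 1)
        + gammaln(N - K + 1)
        - gammaln(n - j + 1)
        - gammaln(N - K - n + j + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(logsumexp(log_pmf), 0.0))


def hypergeometric_tail(record: TermFrequencyRecord) -> float:
    """Upper-tail p-value P(X >= k) of one term's 2x2 table.

    The probability of observing at least ``k`` annotated instances in a
    draw of ``n`` from a population of ``N`` containing ``K`` annotated
    instances.  Record invariants guarantee the result lies in (0, 1].
    """
    return float(
        np.exp(
            log_hypergeometric_tail(
                record.population_size,
                record.population_count,
                record.study_size,
                record.study_count,
            )
        )
    )


def correct_pvalues(
    results: Sequence[EnrichmentResult], config: AnalysisConfig
) -> list[EnrichmentResult]:
    """Apply the configured multiple-testing correction.

    Bonferroni multiplies each raw p-value by the number of tested terms
    (globally, or within the term's namespace under the per-namespace
    scope), optionally capped at 1.
    """
    if config.correction == "none":
        return [replace(r, p_corrected=r.p_value) for r in results]
    if not results:
        raise ValueError("no tested terms: Bonferroni multiplier undefined")
    if config.bonferroni_scope == "all_tested_terms":
        t_for = {r.term_id: len(results) for r in results}
    else:
        per_ns: dict[str, int] = {}
        for r in results:
            per_ns[r.namespace] = per_ns.get(r.namespace, 0) + 1
        t_for = {r.term_id: per_ns[r.namespace] for r in results}
    out = []
    for r in results:
        p_corr = r.p_value * t_for[r.term_id]
        if config.cap_corrected_at_one:
            p_corr = min(p_corr, 1.0)
        out.append(replace(r, p_corrected=p_corr))
    return out


def _assemble(
    records: Sequence[TermFrequencyRecord],
    graph: OntologyGraph,
    ics: Mapping[str, TermIC],
    config: AnalysisConfig,
) -> list[EnrichmentResult]:
    results = []
    for rec in records:
        p = hypergeometric_tail(rec)
        results.append(
            EnrichmentResult(
                term_id=rec.term_id,
                name=graph.name_of(rec.term_id),
                namespace=graph.namespace_of(rec.term_id),
                p_value=p,
                p_corrected=p,
                study_count=rec.study_count,
                study_size=rec.study_size,
                population_count=rec.population_count,
                population_size=rec.population_size,
                ic_normalized=ics[rec.term_id].ic_normalized if rec.term_id in ics else 0.0,
                enriched=p < config.alpha,
            )
        )
    results = correct_pvalues(results, config) if results else results
    # deterministic ranking: ascending p, term accession breaks ties
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def _informative(graph, index, config):
    ics = information_content(graph, index)
    return ics, filter_informative(ics, config.ic_threshold)


def run_profiling(
    cohort: Cohort,
    group: str,
    graph: OntologyGraph,
    index: AnnotationIndex,
    config: AnalysisConfig = AnalysisConfig(),
    genome_size: int | None = None,
) -> list[EnrichmentResult]:
    """Enrichment profiling of a patient group against the genome.

    Candidate terms are those annotating at least one mutated gene of
    the group and passing the information-content filter; each is tested
    with the hypergeometric upper tail and Bonferroni-corrected.
    ``genome_size`` defaults to the annotated universe of the index.
    """
    if genome_size is None:
        genome_size = len(index.universe)
    ics, informative = _informative(graph, index, config)
    study_genes = set(cohort.mutated_gene_multiset(group))
    terms = candidate_terms(index, study_genes, informative)
    if not terms:
        return []
    records = profiling_frequencies(cohort, group, index, genome_size, terms)
    logger.info(
        "profiling %s: %d patients, n=%d instances, N=%d, T=%d terms",
        group, len(cohort.group(group)), records[0].study_size if records else 0,
        records[0].population_size if records else 0, len(records),
    )
    return _assemble(records, graph, ics, config)


def run_differential(
    cohort: Cohort,
    subgroup: str,
    graph: OntologyGraph,
    index: AnnotationIndex,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[EnrichmentResult]:
    """Differential enrichment of a subgroup against the whole cohort."""
    ics, informative = _informative(graph, index, config)
    study_genes = set(cohort.mutated_gene_multiset(subgroup))
    terms = candidate_terms(index, study_genes, informative)
    if not terms:
        return []
    records = differential_frequencies(cohort, subgroup, index, terms)
    logger.info(
        "differential %s: n=%d, N=%d, T=%d terms",
        subgroup, records[0].study_size if records else 0,
        records[0].population_size if records else 0, len(records),
    )
    return _assemble(records, graph, ics, config)


def results_to_frame(results: Sequence[EnrichmentResult], report_style: bool = False) -> pd.DataFrame:
    """Results as a DataFrame in the fixed column order.

    ``report_style`` renders the table dialect used in publications:
    p-values in scientific notation with 2 significant digits, study
    frequency as integer percent, population frequency to 2 decimals.
    Machine style keeps full precision.
    """
    rows = []
    for r in results:
        if report_style:
            rows.append(
                dict(
                    term_id=r.term_id, name=r.name, namespace=r.namespace,
                    p_value=f"{r.p_value:.1E}", p_bonferroni=f"{r.p_corrected:.1E}",
                    k=r.study_count, n=r.study_size,
                    sfreq_pct=f"{round(r.sfreq_pct):d}%",
                    K=r.population_count, N=r.population_size,
                    pfreq_pct=f"{r.pfreq_pct:.2f}%",
                    ic_normalized=f"{r.ic_normalized:.2f}", enriched=r.enriched,
                )
            )
        else:
            rows.append(
                dict(
                    term_id=r.term_id, name=r.name, namespace=r.namespace,
                    p_value=r.p_value, p_bonferroni=r.p_corrected,
                    k=r.study_count, n=r.study_size, sfreq_pct=r.sfreq_pct,
                    K=r.population_count, N=r.population_size,
                    pfreq_pct=r.pfreq_pct, ic_normalized=r.ic_normalized,
                    enriched=r.enriched,
                )
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: Sequence[EnrichmentResult], path, report_style: bool = False) -> None:
    """Write results as TSV in the fixed column order (deterministic bytes)."""
    frame = results_to_frame(results, report_style=report_style)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.12g")
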