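"""Ontology model: OBO parsing, ancestor closure, information content.

The working object is a directed acyclic graph of terms connected by
``is_a`` and (optionally) ``part_of`` edges, one rooted DAG per namespace
(for the Gene Ontology: biological_process, molecular_function,
cellular_component).  Two operations on this graph drive the enrichment
machinery:

* **ancestor closure** — the reflexive-transitive closure of a term over
  the configured relations, implementing the true-path rule (a gene
  annotated to a term is implicitly annotated to every ancestor);
* **information content** — ``IC(t) = -log2(f(t) / f(root))`` where
  ``f(t)`` is the number of distinct gene products annotated with *t*
  (after propagation).  Dividing by the scale maximum ``log2 f(root)``
  normalises IC to [0, 1]: 0 at the root, 1 for a term annotating a
  single gene product.  Terms whose normalised IC does not exceed a
  threshold (default 60%) are considered uninformative and excluded
  from testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "OntologyTerm",
    "OntologyGraph",
    "TermIC",
    "parse_obo",
    "ancestors",
    "information_content",
    "filter_informative",
    "write_ic_table",
]

#: relations that participate in ancestor closure by default (GO true path)
DEFAULT_RELATIONS: tuple[str, ...] = ("is_a", "part_of")


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term.

    ``parents`` maps a relation kind (``is_a``, ``part_of``) to the set of
    parent accessions reachable by one edge of that kind.
    """

    term_id: str
    name: str
    namespace: str
    parents: Mapping[str, frozenset[str]]
    obsolete: bool = False

    def parent_ids(self, relations: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for rel in relations:
            out |= self.parents.get(rel, frozenset())
        return frozenset(out)


class OntologyError(ValueError):
    """Structural problem in an ontology (cycle, dangling parent, ...)."""


@dataclass
class OntologyGraph:
    """A validated multi-namespace ontology DAG.

    Parameters
    ----------
    terms
        Primary terms keyed by accession (obsolete terms excluded).
    roots
        One root accession per namespace.
    alt_ids
        Secondary accession -> primary accession map.
    relations
        Edge kinds used for ancestor closure.
    """

    terms: dict[str, OntologyTerm]
    roots: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)
    relations: tuple[str, ...] = DEFAULT_RELATIONS
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Map an accession (possibly an alt_id) to its primary accession."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise KeyError(f"unknown term: {term_id}")

    def namespace_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].namespace

    def name_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].name

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive-transitive closure of ``term_id`` over ``self.relations``.

        Always contains the term itself and, for any term, its namespace
        root.  Raises ``KeyError`` for unknown accessions.
        """
        tid = self.resolve(term_id)
        cached = self._ancestor_cache.get(tid)
        if cached is not None:
            return cached
        closure: set[str] = {tid}
        stack = [tid]
        while stack:
            current = self.terms[stack.pop()]
            for parent in current.parent_ids(self.relations):
                if parent not in closure:
                    closure.add(parent)
                    stack.append(parent)
        result = frozenset(closure)
        self._ancestor_cache[tid] = result
        return result


def ancestors(graph: OntologyGraph, term_id: str) -> frozenset[str]:
    """Module-level alias for :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term_id)


def _term_from_node(node_id: str, data: Mapping) -> OntologyTerm:
    parents: dict[str, frozenset[str]] = {}
    if data.get("is_a"):
        parents["is_a"] = frozenset(data["is_a"])
    part_of: set[str] = set()
    for rel in data.get("relationship", ()):
        fields = rel.split()
        if len(fields) >= 2 and fields[0] == "part_of":
            part_of.add(fields[1])
    if part_of:
        parents["part_of"] = frozenset(part_of)
    return OntologyTerm(
        term_id=node_id,
        name=data.get("name", ""),
        namespace=data.get("namespace", ""),
        parents=parents,
    )


def parse_obo(source: str | IO[str], relations: tuple[str, ...] = DEFAULT_RELATIONS) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into a validated :class:`OntologyGraph`.

    Obsolete terms are dropped, ``alt_id`` accessions are recorded as
    aliases of their primary term.  The edge set restricted to
    ``relations`` must be acyclic and every referenced parent must be a
    declared, non-obsolete term; violations raise :class:`OntologyError`.
    Each namespace must contain exactly one parentless (root) term.
    """
    g = obonet.read_obo(source, ignore_obsolete=True)

    # obonet creates attribute-less nodes for referenced-but-undeclared terms
    for node, data in g.nodes(data=True):
        if "name" not in data and "namespace" not in data:
            raise OntologyError(
                f"term {node!r} is referenced as a parent but never declared "
                "(or is obsolete)"
            )

    terms = {node: _term_from_node(node, data) for node, data in g.nodes(data=True)}

    # restrict to the closure relations before the cycle check
    closure_edges = [
        (child, parent)
        for child, term in terms.items()
        for parent in term.parent_ids(relations)
    ]
    dag = nx.DiGraph(closure_edges)
    dag.add_nodes_from(terms)
    try:
        cycle = nx.find_cycle(dag)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        child, parent = cycle[0][:2]
        raise OntologyError(f"ontology contains a cycle through edge {child} -> {parent}")

    for term in terms.values():
        for parent in term.parent_ids(relations):
            if parent not in terms:
                raise OntologyError(f"term {term.term_id} references undeclared parent {parent}")

    roots: dict[str, str] = {}
    for term in terms.values():
        if not term.parent_ids(relations):
            if term.namespace in roots:
                raise OntologyError(
                    f"namespace {term.namespace!r} has multiple roots: "
                    f"{roots[term.namespace]}, {term.term_id}"
                )
            roots[term.namespace] = term.term_id

    alt_ids: dict[str, str] = {}
    for node, data in g.nodes(data=True):
        for alt in data.get("alt_id", ()):
            alt_ids[alt] = node

    return OntologyGraph(terms=terms, roots=roots, alt_ids=alt_ids, relations=relations)


@dataclass(frozen=True)
class TermIC:
    """Information content of one term under a given annotation corpus."""

    term_id: str
    namespace: str
    f_t: int
    ic_bits: float
    ic_normalized: float


def information_content(graph: OntologyGraph, index, counts: str = "propagated") -> dict[str, TermIC]:
    """Per-term information content from an annotation corpus.

    ``IC(t) = -log2(f(t)/f(root))`` in bits, normalised by the scale
    maximum ``log2 f(root)`` of the term's own namespace so that the root
    scores 0 and a term annotating exactly one gene product scores 1.
    Terms with ``f(t) = 0`` are omitted.  Requires ``f(root) > 1`` in each
    namespace that carries annotations, otherwise the normalisation is
    undefined.

    ``counts`` selects propagated (ancestor-closed, the default) or
    direct annotation counts from the index.
    """
    if counts not in ("propagated", "direct"):
        raise ValueError(f"counts must be 'propagated' or 'direct', got {counts!r}")
    count_of = index.genome_term_count if counts == "propagated" else index.direct_term_count

    root_f: dict[str, int] = {}
    for namespace, root in graph.roots.items():
        f_root = count_of(root)
        if f_root == 0:
            continue  # namespace carries no annotations at all
        if f_root <= 1:
            raise ValueError(
                f"f(root)={f_root} for namespace {namespace!r}: IC normalisation undefined"
            )
        root_f[namespace] = f_root

    out: dict[str, TermIC] = {}
    for term_id, term in graph.terms.items():
        f_t = count_of(term_id)
        if f_t < 1:
            continue
        f_root = root_f[term.namespace]
        # difference of logs rather than log of the ratio: keeps ic_bits
        # exactly 0 at the root and ic_normalized exactly 1 at f(t)=1
        ic_bits = math.log2(f_root) - math.log2(f_t)
        ic_norm = ic_bits / math.log2(f_root)
        out[term_id] = TermIC(term_id, term.namespace, f_t, ic_bits, ic_norm)
    return out


def filter_informative(term_ics: Mapping[str, TermIC], threshold: float = 0.6) -> frozenset[str]:
    """Accessions whose normalised IC is *strictly* above ``threshold``."""
    return frozenset(t for t, ic in term_ics.items() if ic.ic_normalized > threshold)


def write_ic_table(term_ics: Mapping[str, TermIC], path) -> None:
    """Write the IC table as TSV: term_id, namespace, f_t, ic_bits, ic_normalized."""
    with open(path, "w") as fh:
        fh.write("term_id\tnamespace\tf_t\tic_bits\tic_normalized\n")
        for term_id in sorted(term_ics):
            ic = term_ics[term_id]
            fh.write(
                f"{ic.term_id}\t{ic.namespace}\t{ic.f_t}\t{ic.ic_bits:.6f}\t{ic.ic_normalized:.6f}\n"
            )
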