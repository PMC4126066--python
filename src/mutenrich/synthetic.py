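"""Self-contained synthetic fixtures: cohorts, toy ontologies, annotations.

Two generators live here.

``make_hcm_fixture`` rebuilds, deterministically and without RNG, a
hypertrophic-cardiomyopathy study cohort: 83 patients (14 positive for
sudden cardiac death, 69 negative) genotyped over a 7-gene sarcomere
panel with published per-group mutated-patient marginals
(MYBPC3 4/25, MYH7 9/36, CSRP3 1/4, TNNT2 2/20, TNNI3 0/13, MYL2 0/1,
MYH6 0/1), yielding study multisets of 16 (positive), 100 (negative)
and 116 (cohort) gene instances over 4 / 7 / 7 distinct genes.  The
accompanying ontology and annotation corpus are a *synthetic* stand-in
for a real GO release: a small muscle-biology vocabulary plus generic
background terms, sized so the specific terms pass the 60%
information-content filter.  Only the cohort marginals are faithful to
the study; annotation counts are not.

``generate_cohort`` draws random cohorts with a configurable planted
enriched term for power and type-I-error experiments: per-gene Bernoulli
mutations, with the planted term's annotated genes mutated at
``planted_effect`` times the base probability in the event-positive
group.  With ``planted_effect = 1`` the generator is an exact null for
the differential test.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .annotations import AnnotationIndex, build_index, parse_gaf
from .cohort import Cohort, EventRule, Patient
from .ontology import DEFAULT_RELATIONS, OntologyGraph, parse_obo

__all__ = [
    "SyntheticSpec",
    "make_hcm_fixture",
    "generate_cohort",
    "write_fixture",
    "HCM_GENE_PANEL",
    "HCM_POSITIVE_MARGINALS",
    "HCM_NEGATIVE_MARGINALS",
    "HCM_GENOME_SIZE",
    "HCM_EVENT_RULE",
]

# ---------------------------------------------------------------------------
# HCM fixture constants (per-group mutated-patient marginals)

HCM_GENE_PANEL = ("MYBPC3", "MYH7", "CSRP3", "TNNT2", "TNNI3", "MYL2", "MYH6")
HCM_POSITIVE_MARGINALS = {
    "MYBPC3": 4, "MYH7": 9, "CSRP3": 1, "TNNT2": 2, "TNNI3": 0, "MYL2": 0, "MYH6": 0,
}
HCM_NEGATIVE_MARGINALS = {
    "MYBPC3": 25, "MYH7": 36, "CSRP3": 4, "TNNT2": 20, "TNNI3": 13, "MYL2": 1, "MYH6": 1,
}
HCM_N_POSITIVE = 14
HCM_N_NEGATIVE = 69
#: annotated protein-coding genes in the reference genome (profiling N = this x m)
HCM_GENOME_SIZE = 18759

HCM_EVENT_FEATURES = ("sudden_death", "resuscitated_sudden_death", "cardioverter_defibrillator")
HCM_EVENT_RULE = EventRule(positive_if_any=HCM_EVENT_FEATURES)

_N_BACKGROUND = 93  # background genes padding each namespace's annotation corpus

# muscle-biology toy ontology: (term_id, name, namespace, is_a parents, part_of parents)
_HCM_TERMS = [
    ("GO:0008150", "biological_process", "biological_process", (), ()),
    ("GO:0008152", "metabolic process", "biological_process", ("GO:0008150",), ()),
    ("GO:0003012", "muscle system process", "biological_process", ("GO:0008150",), ()),
    ("GO:0030049", "muscle filament sliding", "biological_process", ("GO:0003012",), ()),
    ("GO:0002027", "regulation of heart rate", "biological_process", ("GO:0003012",), ()),
    ("GO:0007507", "heart development", "biological_process", ("GO:0008150",), ()),
    ("GO:0055010", "ventricular cardiac muscle tissue morphogenesis", "biological_process",
     ("GO:0007507",), ()),
    ("GO:0003674", "molecular_function", "molecular_function", (), ()),
    ("GO:0005488", "binding", "molecular_function", ("GO:0003674",), ()),
    ("GO:0005198", "structural molecule activity", "molecular_function", ("GO:0003674",), ()),
    ("GO:0008307", "structural constituent of muscle", "molecular_function", ("GO:0005198",), ()),
    ("GO:0003774", "cytoskeletal motor activity", "molecular_function", ("GO:0003674",), ()),
    ("GO:0000146", "microfilament motor activity", "molecular_function", ("GO:0003774",), ()),
    ("GO:0003779", "actin binding", "molecular_function", ("GO:0005488",), ()),
    ("GO:0030172", "troponin C binding", "molecular_function", ("GO:0005488",), ()),
    ("GO:0005575", "cellular_component", "cellular_component", (), ()),
    ("GO:0110165", "cellular anatomical entity", "cellular_component", ("GO:0005575",), ()),
    ("GO:0043292", "contractile fiber", "cellular_component", ("GO:0110165",), ()),
    ("GO:0030016", "myofibril", "cellular_component", ("GO:0043292",), ()),
    ("GO:0005859", "muscle myosin complex", "cellular_component", ("GO:0110165",), ("GO:0030016",)),
    ("GO:0005861", "troponin complex", "cellular_component", ("GO:0110165",), ("GO:0030016",)),
    ("GO:0031672", "A band", "cellular_component", ("GO:0110165",), ("GO:0030016",)),
]

# direct annotations of the panel genes (term -> genes)
_HCM_DIRECT_ANNOTATIONS = {
    "GO:0030049": ("MYH7", "MYL2", "MYH6"),
    "GO:0002027": ("TNNT2", "TNNI3"),
    "GO:0055010": ("MYBPC3", "MYH7", "TNNT2"),
    "GO:0008307": ("MYBPC3", "MYH7", "CSRP3"),
    "GO:0000146": ("MYH7", "MYH6"),
    "GO:0003779": ("MYBPC3", "CSRP3", "MYL2"),
    "GO:0030172": ("TNNI3", "TNNT2"),
    "GO:0005859": ("MYH7", "MYL2", "MYH6"),
    "GO:0005861": ("TNNT2", "TNNI3"),
    "GO:0031672": ("MYBPC3", "MYH6"),
}
# background genes annotate one generic (uninformative) term per namespace
_HCM_BACKGROUND_TERMS = ("GO:0008152", "GO:0005488", "GO:0110165")

_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}


def _obo_text(terms) -> str:
    lines = ["format-version: 1.2", "ontology: syn", ""]
    for term_id, name, namespace, is_a, part_of in terms:
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        lines.append(f"name: {name}")
        lines.append(f"namespace: {namespace}")
        for parent in is_a:
            lines.append(f"is_a: {parent}")
        for parent in part_of:
            lines.append(f"relationship: part_of {parent}")
        lines.append("")
    return "\n".join(lines)


def _gaf_text(term_gene_pairs, namespace_of) -> str:
    """GAF 2.1 text for (term, gene) direct annotations, deterministic order."""
    lines = ["!gaf-version: 2.1"]
    for term, gene in sorted(term_gene_pairs, key=lambda tg: (tg[1], tg[0])):
        aspect = _ASPECT.get(namespace_of(term), namespace_of(term)[:1].upper() or "P")
        cols = [
            "SYN", gene, gene, "", term, "SYN:0000001", "IEA", "", aspect,
            "", "", "gene", "taxon:9606", "20121004", "SYN", "", "",
        ]
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def _allocate_marginals(marginals: dict[str, int], patient_ids: list[str]) -> dict[str, set[str]]:
    """Greedy round-robin allocation of per-gene mutated-patient counts.

    Cycling a single pointer over the patients while walking genes in
    panel order spreads the instances so no patient exceeds the 1-5
    mutated-gene bound and, when the total covers the group, every
    patient receives at least one mutation.
    """
    n = len(patient_ids)
    assignment: dict[str, set[str]] = {pid: set() for pid in patient_ids}
    pointer = 0
    for gene, count in marginals.items():
        if count > n:
            raise ValueError(f"gene {gene}: count {count} exceeds group size {n}")
        for _ in range(count):
            assignment[patient_ids[pointer % n]].add(gene)
            pointer += 1
    return assignment


def _hcm_clinical_positive(i: int) -> dict[str, Optional[bool]]:
    """Clinical features of the i-th (0-based) event-positive patient.

    Pattern reproducing the published per-feature counts: 5 sudden
    deaths, 3 resuscitated, 9 defibrillator carriers, with missing
    values for the deceased patients' device/resuscitation fields.
    """
    sd = i < 5
    resus = 5 <= i < 8
    defib = i >= 5
    return {
        "sudden_death": sd,
        "resuscitated_sudden_death": None if i < 3 else resus,
        "cardioverter_defibrillator": None if i < 3 else defib,
    }


def make_hcm_fixture(
    relations: tuple[str, ...] = DEFAULT_RELATIONS,
) -> tuple[Cohort, OntologyGraph, AnnotationIndex]:
    """The deterministic HCM case-study fixture (no RNG involved).

    Returns a cohort whose per-group mutated-patient marginals match the
    published panel exactly, together with the synthetic muscle-biology
    ontology and its propagated annotation index.
    """
    graph = parse_obo_text(_obo_text(_HCM_TERMS), relations)

    pairs = [(t, g) for t, genes in _HCM_DIRECT_ANNOTATIONS.items() for g in genes]
    for i in range(1, _N_BACKGROUND + 1):
        for term in _HCM_BACKGROUND_TERMS:
            pairs.append((term, f"BG{i:03d}"))
    annotations, _ = parse_gaf_text(_gaf_text(pairs, graph.namespace_of))
    index = build_index(annotations, graph)

    pos_ids = [f"P{i:03d}" for i in range(1, HCM_N_POSITIVE + 1)]
    neg_ids = [f"P{i:03d}" for i in range(HCM_N_POSITIVE + 1, HCM_N_POSITIVE + HCM_N_NEGATIVE + 1)]
    pos_assign = _allocate_marginals(HCM_POSITIVE_MARGINALS, pos_ids)
    neg_assign = _allocate_marginals(HCM_NEGATIVE_MARGINALS, neg_ids)

    patients: list[Patient] = []
    for i, pid in enumerate(pos_ids):
        mutations = {g: g in pos_assign[pid] for g in HCM_GENE_PANEL}
        patients.append(Patient(pid, mutations, _hcm_clinical_positive(i)))
    for pid in neg_ids:
        mutations = {g: g in neg_assign[pid] for g in HCM_GENE_PANEL}
        clinical = {f: False for f in HCM_EVENT_FEATURES}
        patients.append(Patient(pid, mutations, clinical))

    cohort = Cohort(patients=patients, gene_panel=HCM_GENE_PANEL, event_rule=HCM_EVENT_RULE)
    return cohort, graph, index


# ---------------------------------------------------------------------------
# random cohorts with a planted enriched term

PLANTED_TERM_ID = "SYN:2000000"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one random cohort draw.

    Defaults describe a registry-scale disease-panel cohort: 600
    event-positive and 1200 event-negative patients genotyped over a
    60-gene panel, each gene mutated independently with probability 0.02
    per patient (about 1.2 mutated genes per patient — the sparsity
    regime of real disease panels), a planted term annotating a 15-gene
    slice of the panel, and 1000 background genes so the planted term
    clears the information-content filter.  ``planted_effect``
    multiplies the mutation probability of the planted term's genes in
    the positive group (1 = null).  The same seed reproduces the cohort
    byte for byte.
    """

    seed: int
    n_patients_pos: int = 600
    n_patients_neg: int = 1200
    gene_panel_size: int = 60
    n_background_genes: int = 1000
    genome_size: int = 2500
    n_terms_per_namespace: int = 8
    mutation_prob_pos: float = 0.02
    mutation_prob_neg: float = 0.02
    planted_term: Optional[str] = PLANTED_TERM_ID
    planted_effect: float = 1.0
    planted_gene_fraction: float = 0.25

    def __post_init__(self):
        for name in ("mutation_prob_pos", "mutation_prob_neg"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.planted_effect < 0:
            raise ValueError("planted_effect must be non-negative")
        if self.n_patients_pos < 1 or self.n_patients_neg < 0:
            raise ValueError("need at least one positive patient")
        if self.genome_size < self.gene_panel_size + self.n_background_genes:
            raise ValueError("genome_size smaller than the annotated universe")


_NS_TAGS = (("biological_process", 1), ("molecular_function", 3), ("cellular_component", 5))


def _synthetic_ontology(spec: SyntheticSpec, rng: np.random.Generator):
    """Random DAG per namespace: root, one generic background term, and
    ``n_terms_per_namespace`` terms each with 1-2 parents among the
    earlier terms.  The planted term is a fixed child of the process
    root so its accession is stable across seeds."""
    terms = []
    generic: dict[str, str] = {}
    ids_by_ns: dict[str, list[str]] = {}
    for ns, tag in _NS_TAGS:
        root = f"SYN:{tag}000000"
        gen = f"SYN:{tag}000001"
        terms.append((root, ns, ns, (), ()))
        terms.append((gen, f"generic {ns} term", ns, (root,), ()))
        generic[ns] = gen
        pool = [root]
        for i in range(spec.n_terms_per_namespace):
            tid = f"SYN:{tag}{i + 2:06d}"
            n_par = 1 if len(pool) == 1 else int(rng.integers(1, 3))
            parents = tuple(
                sorted(str(p) for p in rng.choice(pool, size=min(n_par, len(pool)), replace=False))
            )
            terms.append((tid, f"synthetic term {tid}", ns, parents, ()))
            pool.append(tid)
        ids_by_ns[ns] = [t for t in pool[1:]]
    # the planted candidate process
    terms.append((PLANTED_TERM_ID, "planted candidate process", "biological_process",
                  ("SYN:1000000",), ()))
    return terms, generic, ids_by_ns


def generate_cohort(
    spec: SyntheticSpec,
    relations: tuple[str, ...] = DEFAULT_RELATIONS,
) -> tuple[Cohort, OntologyGraph, AnnotationIndex]:
    """Draw a random cohort, ontology and annotation corpus from a spec.

    Panel genes are annotated to 1-2 random terms per namespace; the
    planted term annotates the first ``planted_gene_fraction`` slice of
    the panel, and its genes are mutated ``planted_effect`` times more
    probably in the positive group.  Raises if the planted term would
    annotate no panel gene.
    """
    rng = np.random.default_rng(spec.seed)
    term_defs, generic, ids_by_ns = _synthetic_ontology(spec, rng)
    graph = parse_obo_text(_obo_text(term_defs), relations)

    panel = tuple(f"PG{i:03d}" for i in range(1, spec.gene_panel_size + 1))
    n_planted_genes = math.ceil(spec.planted_gene_fraction * spec.gene_panel_size)
    planted_genes = frozenset(panel[:n_planted_genes])
    if spec.planted_term is not None:
        if spec.planted_term not in graph:
            raise ValueError(f"planted term {spec.planted_term} not in the generated ontology")
        if spec.planted_term == PLANTED_TERM_ID and not planted_genes:
            raise ValueError("planted term annotates no panel gene")

    pairs: list[tuple[str, str]] = []
    for gene in panel:
        for ns, _ in _NS_TAGS:
            pool = [t for t in ids_by_ns[ns] if t != PLANTED_TERM_ID]
            n_ann = int(rng.integers(1, 3))
            for t in rng.choice(pool, size=min(n_ann, len(pool)), replace=False):
                pairs.append((str(t), gene))
    for gene in planted_genes:
        pairs.append((PLANTED_TERM_ID, gene))
    if spec.planted_term is not None and spec.planted_term != PLANTED_TERM_ID:
        # a user-designated planted term must already annotate panel genes
        if not any(t == spec.planted_term for t, _ in pairs):
            raise ValueError(f"planted term {spec.planted_term} annotates no panel gene")
    for i in range(1, spec.n_background_genes + 1):
        gene = f"BG{i:03d}"
        for ns, _ in _NS_TAGS:
            pairs.append((generic[ns], gene))
    pairs = sorted(set(pairs))
    annotations, _ = parse_gaf_text(_gaf_text(pairs, graph.namespace_of))
    index = build_index(annotations, graph)

    # mutation grid: per-gene Bernoulli, planted genes inflated in positives
    planted_targets = (
        index.genes_for_term(spec.planted_term) & frozenset(panel)
        if spec.planted_term is not None
        else frozenset()
    )
    prob_pos = np.full(len(panel), spec.mutation_prob_pos)
    for j, gene in enumerate(panel):
        if gene in planted_targets:
            prob_pos[j] = min(spec.mutation_prob_pos * spec.planted_effect, 0.95)
    prob_neg = np.full(len(panel), spec.mutation_prob_neg)

    pos_grid = rng.random((spec.n_patients_pos, len(panel))) < prob_pos
    neg_grid = rng.random((spec.n_patients_neg, len(panel))) < prob_neg

    patients: list[Patient] = []
    for i in range(spec.n_patients_pos):
        pid = f"S{i + 1:04d}"
        mutations = {g: bool(pos_grid[i, j]) for j, g in enumerate(panel)}
        patients.append(Patient(pid, mutations, {"event": True}))
    for i in range(spec.n_patients_neg):
        pid = f"S{spec.n_patients_pos + i + 1:04d}"
        mutations = {g: bool(neg_grid[i, j]) for j, g in enumerate(panel)}
        patients.append(Patient(pid, mutations, {"event": False}))

    cohort = Cohort(
        patients=patients, gene_panel=panel, event_rule=EventRule(positive_if_any=("event",))
    )
    return cohort, graph, index


# ---------------------------------------------------------------------------
# serialization

def parse_obo_text(text: str, relations: tuple[str, ...] = DEFAULT_RELATIONS) -> OntologyGraph:
    import io

    return parse_obo(io.StringIO(text), relations)


def parse_gaf_text(text: str):
    import io

    return parse_gaf(io.StringIO(text))


def _graph_to_obo(graph: OntologyGraph) -> str:
    terms = []
    for tid in sorted(graph.terms):
        t = graph.terms[tid]
        terms.append(
            (
                tid,
                t.name,
                t.namespace,
                tuple(sorted(t.parents.get("is_a", ()))),
                tuple(sorted(t.parents.get("part_of", ()))),
            )
        )
    return _obo_text(terms)


def _index_to_gaf(index: AnnotationIndex, graph: OntologyGraph) -> str:
    pairs = [
        (term, gene)
        for term, genes in index.direct_term_to_genes.items()
        for gene in genes
    ]
    return _gaf_text(pairs, graph.namespace_of)


def _cohort_to_tsv(cohort: Cohort) -> str:
    def cell(v: Optional[bool]) -> str:
        return "NA" if v is None else ("1" if v else "0")

    clinical_cols = list(cohort.patients[0].clinical)
    header = ["patient_id", *clinical_cols, *cohort.gene_panel]
    lines = ["\t".join(header)]
    for p in cohort.patients:
        row = [p.patient_id]
        row += [cell(p.clinical.get(c)) for c in clinical_cols]
        row += [cell(p.mutations.get(g)) for g in cohort.gene_panel]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def write_fixture(
    cohort: Cohort,
    graph: OntologyGraph,
    index: AnnotationIndex,
    directory,
    manifest: Optional[dict] = None,
) -> dict[str, Path]:
    """Write a fixture as the OBO/GAF/TSV files the readers consume.

    Outputs are byte-deterministic and round-trip through
    ``parse_obo`` / ``parse_gaf`` + ``build_index`` / ``read_cohort``
    to objects equal to the inputs.  A manifest JSON records provenance.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": directory / "ontology.obo",
        "gaf": directory / "annotations.gaf",
        "cohort": directory / "cohort.tsv",
        "manifest": directory / "manifest.json",
    }
    paths["obo"].write_text(_graph_to_obo(graph))
    paths["gaf"].write_text(_index_to_gaf(index, graph))
    paths["cohort"].write_text(_cohort_to_tsv(cohort))
    meta = {
        "n_patients": len(cohort),
        "gene_panel": list(cohort.gene_panel),
        "event_rule": list(cohort.event_rule.positive_if_any),
        "n_terms": len(graph),
        "n_annotated_genes": len(index.universe),
    }
    if manifest:
        meta.update(manifest)
    paths["manifest"].write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return paths


def spec_manifest(spec: SyntheticSpec) -> dict:
    """Manifest payload recording a generator spec."""
    return {"generator": "generate_cohort", "spec": asdict(spec)}
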