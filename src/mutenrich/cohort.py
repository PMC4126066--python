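"""Patient cohort model: mutation profiles, clinical features, event labels.

A cohort is a set of patients genotyped over a fixed gene panel, each
carrying boolean clinical features with an explicit missing state.  A
patient's event label (e.g. sudden cardiac death) is derived from an
any-true rule over a list of clinical features; missing values never
make a patient event-positive.

Mutations not tested in a patient are treated as absent downstream —
sparse clinical datasets rarely genotype every patient for every
mutation, and discarding untested patients or genes would discard most
of the data.  The tri-state (present / absent / untested) is preserved
in the model so the policy is explicit, not baked into the file reader.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "Patient",
    "EventRule",
    "Cohort",
    "read_cohort",
    "label_event",
    "mutated_gene_multiset",
]

logger = logging.getLogger(__name__)

#: values accepted in cohort TSV cells
_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}
_MISSING = {"", "NA", "na", "NaN", "nan", "None"}


@dataclass(frozen=True)
class Patient:
    """One patient: tri-state mutation status per panel gene and tri-state
    clinical features (``None`` encodes untested / missing)."""

    patient_id: str
    mutations: Mapping[str, Optional[bool]]
    clinical: Mapping[str, Optional[bool]]

    def is_mutated(self, gene: str) -> bool:
        """Present-only view: untested counts as not mutated."""
        return self.mutations.get(gene) is True

    def mutated_genes(self) -> frozenset[str]:
        return frozenset(g for g, v in self.mutations.items() if v is True)


@dataclass(frozen=True)
class EventRule:
    """A patient is event-positive iff any listed feature is true."""

    positive_if_any: tuple[str, ...]

    def __post_init__(self):
        if not self.positive_if_any:
            raise ValueError("EventRule requires at least one feature")

    def is_positive(self, patient: Patient) -> bool:
        return any(patient.clinical.get(f) is True for f in self.positive_if_any)


@dataclass
class Cohort:
    """An ordered collection of patients over a shared gene panel."""

    patients: list[Patient]
    gene_panel: tuple[str, ...]
    event_rule: EventRule
    _labels: dict[str, str] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if not self.patients:
            raise ValueError("a cohort needs at least one patient")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate patient_id: {dup}")
        for rule_feature in self.event_rule.positive_if_any:
            if not any(rule_feature in p.clinical for p in self.patients):
                raise ValueError(f"event-rule feature {rule_feature!r} absent from cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def labels(self) -> dict[str, str]:
        """patient_id -> 'positive' | 'negative' under the event rule."""
        if not self._labels:
            self._labels = {
                p.patient_id: "positive" if self.event_rule.is_positive(p) else "negative"
                for p in self.patients
            }
        return self._labels

    def group(self, which: str) -> list[Patient]:
        """Patients in a group: 'positive', 'negative' or 'all'."""
        if which == "all":
            return list(self.patients)
        if which not in ("positive", "negative"):
            raise ValueError(f"unknown group {which!r}")
        labels = self.labels()
        return [p for p in self.patients if labels[p.patient_id] == which]

    def mutated_gene_multiset(self, which: str = "all") -> Counter:
        """Multiset of mutated genes over a patient group.

        Each gene contributes one instance per patient mutated in it —
        the patient x gene instance counting used by both enrichment
        analyses (a patient counts once per gene no matter how many of
        that gene's mutations it carries).
        """
        members = self.group(which)
        if not members:
            raise ValueError(f"group {which!r} is empty")
        counts: Counter = Counter()
        for p in members:
            for g in self.gene_panel:
                if p.is_mutated(g):
                    counts[g] += 1
        return counts


def label_event(cohort: Cohort) -> dict[str, str]:
    """Module-level alias for :meth:`Cohort.labels`."""
    return cohort.labels()


def mutated_gene_multiset(cohort: Cohort, group: str = "all") -> Counter:
    """Module-level alias for :meth:`Cohort.mutated_gene_multiset`."""
    return cohort.mutated_gene_multiset(group)


def _tristate(value: str, where: str) -> Optional[bool]:
    if value in _TRUE:
        return True
    if value in _FALSE:
        return False
    if value in _MISSING:
        return None
    raise ValueError(f"unparseable cell {value!r} in {where}")


def read_cohort(
    source: str | IO[str],
    panel: Iterable[str],
    event_rule: EventRule,
    mutation_gene_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a cohort TSV.

    The header row carries ``patient_id``, clinical feature columns and
    one column per panel gene (or, with ``mutation_gene_map``, one column
    per individual mutation, collapsed onto its gene: a patient is
    mutated in a gene if any of that gene's mutation columns is 1).
    Cells are ``1`` / ``0`` / ``NA``; NA in a mutation column means
    untested, NA in a clinical column means missing.  Duplicate patient
    ids are a hard error; mutation columns mapping to genes outside the
    panel are ignored with a warning.
    """
    panel = tuple(panel)
    panel_set = set(panel)
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns:
        raise ValueError("cohort TSV must have a patient_id column")

    mutation_cols: dict[str, str] = {}  # column -> gene
    if mutation_gene_map:
        for col, gene in mutation_gene_map.items():
            if col not in df.columns:
                continue
            if gene not in panel_set:
                logger.warning("mutation column %r maps to unknown gene %r; ignored", col, gene)
                continue
            mutation_cols[col] = gene
    for col in df.columns:
        if col in panel_set:
            mutation_cols[col] = col
    clinical_cols = [
        c for c in df.columns if c != "patient_id" and c not in mutation_cols
    ]

    patients: list[Patient] = []
    for _, row in df.iterrows():
        pid = row["patient_id"]
        # collapse mutation columns onto genes: present if any 1, else
        # absent if any tested 0, else untested
        per_gene: dict[str, Optional[bool]] = {g: None for g in panel}
        for col, gene in mutation_cols.items():
            v = _tristate(row[col], f"patient {pid}, column {col}")
            if v is True:
                per_gene[gene] = True
            elif v is False and per_gene[gene] is None:
                per_gene[gene] = False
        clinical = {
            c: _tristate(row[c], f"patient {pid}, column {c}") for c in clinical_cols
        }
        patients.append(Patient(patient_id=pid, mutations=per_gene, clinical=clinical))

    return Cohort(patients=patients, gene_panel=panel, event_rule=event_rule)
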