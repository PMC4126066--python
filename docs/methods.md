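# Methods

## The problem

Cohorts collected in clinical practice for diseases with a strong
genetic component — the motivating case is hypertrophic cardiomyopathy
(HCM) — typically record, per patient, a panel of disease-associated
genes with present/absent/untested mutation calls and a handful of
boolean clinical features with many missing values.  The question is
whether the *functions* of the mutated genes, as described by an
ontology such as the Gene Ontology, differ between patients who suffered
a disease-related event (here: sudden cardiac death, SCD) and those who
did not.

Classic singular enrichment analysis (SEA) tests one gene set against
one reference set.  Here every patient carries their own mutated-gene
set, so both sets become **multisets of patient×gene instances**: a gene
contributes one instance per patient mutated in it.  Two analyses are
built on this idea.

## The two analyses

Let a group contain `m` patients, `G` be the number of annotated genes
in the genome, and `f(t)` the number of distinct genes annotated
(after ancestor propagation) with term `t`.

**Enrichment profiling** characterises a patient group against the
genome:

- study set: all mutated gene instances in the group, size
  `n = Σ_g (#patients in group mutated in g)`;
- population set: each patient's entire annotated genome, size
  `N = G × m`;
- per term: `k = Σ` over the group of mutated genes annotated with `t`,
  and `K = m × f(t)` because all patients share the same genome.

**Differential enrichment** contrasts a subgroup with the whole cohort:

- population set: all mutated instances in the cohort (size `N`);
- study set: the subgroup's mutated instances (size `n`);
- `K` and `k` count annotated instances within those multisets.

Each candidate term is scored with the hypergeometric upper tail

    p(t) = P(X ≥ k),  X ~ Hypergeometric(N, K, n)

i.e. a one-sided (over-representation only) Fisher exact test.  A term
is flagged enriched when the *uncorrected* p-value is below `alpha`
(default 0.1); the Bonferroni-corrected value `p × T` (`T` = number of
tested terms) is reported alongside, optionally uncapped for
publication-style tables.  Candidate terms are those annotating at least
one mutated study gene *and* passing the information-content filter, so
`T` counts informative terms only.

## Annotation model

Annotations follow the true-path rule: a gene annotated to a term is
annotated to all its ancestors over `is_a` and `part_of` edges (a flag
restricts closure to `is_a`).  All evidence codes are kept by default,
including IEA, trading possible annotation errors for coverage; rows
with a `NOT` qualifier never enter the index.  Term frequencies `f(t)`
are counted after propagation (a `counts="direct"` switch exposes the
pre-propagation counts).

Uninformative terms are removed with normalised information content:

    IC(t) = -log2( f(t) / f(root) ),   IC_norm(t) = IC(t) / log2 f(root)

computed per namespace (the namespaces are disjoint DAGs, each with its
own root).  `IC_norm` is 0 at the root and 1 for a term annotating a
single gene; only terms with `IC_norm` **strictly above** 0.60 are
tested.  IC is computed as a difference of logs so the [0, 1] bounds
hold exactly in floating point.

Missing data policy: untested mutations count as absent (discarding
sparse panels would discard most of the data), and missing clinical
values never make a patient event-positive (the event label is an
any-true rule over designated features).

## Numerical notes

- The tail is summed in log space from `gammaln` terms with
  `logsumexp`; profiling-scale inputs (`N ≈ 2.6×10^5`) produce
  p-values around 1e-40, far below what a naive survival-function
  difference can represent.  Agreement with exact integer enumeration is
  better than 1e-12 relative error over every table with `N ≤ 60`.
- `k = 0` returns p = 1; a subgroup equal to the cohort makes every
  p = 1 and warns.
- Results are ranked by `(p, term_id)` so ties break deterministically,
  and every writer iterates in sorted order, making all output files
  byte-reproducible.

## Synthetic data

`make_hcm_fixture()` rebuilds the case-study cohort deterministically:
83 patients (14 SCD-positive), a 7-gene sarcomere panel whose per-group
mutated-patient marginals are fixed
(pos: MYBPC3 4, MYH7 9, CSRP3 1, TNNT2 2; neg: 25/36/4/20/13/1/1),
giving study multisets of 16, 100 and 116 instances over 4/7/7 distinct
genes.  Only the marginals are constrained; the per-patient allocation
is a greedy round-robin that keeps every patient within the 1–5
mutated-gene range.  The clinical columns reproduce the published
per-feature counts (5 sudden deaths, 3 resuscitated, 9 defibrillator
carriers, with missing values for deceased patients' device fields).
The accompanying ontology is a small synthetic muscle-biology
vocabulary plus 93 background genes per namespace, sized so that the
specific terms clear the 60% IC filter; its annotation counts are a
stand-in, not a reproduction of any real ontology release, so
release-bound quantities (absolute p-values of real GO terms, tested
term counts) are out of scope for testing.  The profiling genome size
defaults to 18,759 annotated genes, carried as a constant rather than
as 18,759 annotation rows.

`generate_cohort(spec)` draws random cohorts for power and type-I-error
experiments.  Defaults model a registry-scale panel study: 600
event-positive and 1200 event-negative patients, a 60-gene panel with
uniform per-gene mutation probability 0.02 (≈1.2 mutated genes per
patient, the sparsity of real disease panels), a planted term
annotating a 15-gene slice of the panel, and 1000 background genes
(universe 1060; planted-term IC 0.611).  `planted_effect` multiplies
the planted genes' mutation probability in the positive group; 1 is an
exact null.

Why these sizes: with uniform per-gene probability, mutations form an
exchangeable random subset of the patient×gene grid, and conditioning
on the 2×2 margins gives `k` a unit-odds-ratio law over grid cells.
Because each cell holds at most one instance, that true null is
slightly *underdispersed* relative to the instance-level hypergeometric
the test assumes, so the exact test is conservative in proportion to
cell occupancy (the per-gene mutation probability); together
with the discrete staircase of attainable p-values this pushes the null
rejection rate below alpha in small, dense cohorts (≈0.06 at 100
patients with 15% mutation probability).  In the sparse default regime
the attainable rate is ≈0.09 at alpha = 0.1, and the suite's
1000-replicate calibration check observes 0.085 — within three
Monte-Carlo standard errors of nominal.  Power against
`planted_effect = 2` is ≈1.0 at these sizes; the regression test
requires ≥0.90 over 300 replicates.

What the generator does **not** model: per-mutation (rather than
per-gene) genotyping, benign/malignant mutation classes, pleiotropy,
correlated mutations within pathways, clinical-feature distributions
beyond the event rule, or annotation bias.  Passing the calibration and
power suites therefore shows the statistics behave as designed under
the stated sampling model, not that real cohorts satisfy that model.

## Design choices

- **Multiset counting**: a patient counts once per mutated gene
  regardless of how many of that gene's mutations they carry; the
  per-mutation→gene collapse happens in the cohort reader.
- **Bonferroni scope** defaults to one global `T` across namespaces
  (per-namespace available); the flag exists because either convention
  appears in published tables.
- **Strict IC threshold** (`> 0.6`, not `≥`), reading "above 60%"
  literally; the boundary is tested.
- **One root per namespace** is enforced at parse time; obsolete terms
  are dropped and `alt_id` accessions resolve to their primary term.
- **Malformed GAF rows** are skipped and counted, never fatal; an
  unresolvable term id likewise (real OBO/GAF releases drift apart).

## Problem sizes used by the test suite

The enumeration check covers every hypergeometric table with `N ≤ 60`
(~2.4×10^5 tuples); the invariants suite uses 100 random DAG corpora of
up to 50 terms and 30 genes; calibration uses 1000 replicate cohorts at
the default generator scale and power 300.  These sizes keep the whole
suite within a few minutes on one CPU while leaving the statistical
assertions well-powered.

## Known limitations

- The enrichment flag follows the uncorrected p-value, as in the
  original analyses; with a global Bonferroni `T` this is liberal, and
  both values are always reported so users can apply either rule.
- Instances within a patient are treated as exchangeable draws; the
  cluster structure of patients is ignored by the test (see the
  conservativeness discussion above for its direction and size).
- Only `is_a`/`part_of` closure is supported; `regulates` and other
  relations are out of scope, as are OWL inputs and FDR-style
  corrections.
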