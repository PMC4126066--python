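"""Enrichment profiling of an event-positive patient group.

Builds the deterministic cardiomyopathy case-study cohort (83 patients,
14 positive for sudden cardiac death) and asks which ontology terms are
over-represented among the genes mutated in the positive group, compared
with the whole annotated genome carried by each of those patients.
"""

from mutenrich import make_hcm_fixture, results_to_frame, run_profiling
from mutenrich.synthetic import HCM_GENOME_SIZE

cohort, graph, index = make_hcm_fixture()

results = run_profiling(cohort, "positive", graph, index, genome_size=HCM_GENOME_SIZE)

print(f"patients: {len(cohort)} ({len(cohort.group('positive'))} event-positive)")
n, N = results[0].study_size, results[0].population_size
print(f"study set: {n} mutated gene instances; population set: {N} = {HCM_GENOME_SIZE} x 14")
print(f"{len(results)} informative terms tested, "
      f"{sum(r.enriched for r in results)} enriched at alpha=0.1\n")
print(results_to_frame(results, report_style=True).head(5).to_string(index=False))
print("\nEach row: a term, its upper-tail p-value (raw and Bonferroni),")
print("and the share of study/population instances it annotates. The tiny")
print("p-values arise because nearly all mutated instances carry muscle terms")
print("that are rare in the 18,759-gene annotated genome.")
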