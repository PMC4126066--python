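"""Differential enrichment: an event-positive subgroup vs the whole cohort.

Instead of comparing mutated genes against the genome, the differential
analysis compares the subgroup's mutated gene instances (study set, n=16)
with all mutated instances in the cohort (population set, N=116): a
significant term marks functions mutated more often in the subgroup.
"""

from mutenrich import make_hcm_fixture, results_to_frame, run_differential

cohort, graph, index = make_hcm_fixture()

results = run_differential(cohort, "positive", graph, index)

n, N = results[0].study_size, results[0].population_size
print(f"study set n={n} (positive subgroup), population set N={N} (all mutated instances)")
print(results_to_frame(results).head(5).to_string(index=False))
enriched = [r for r in results if r.enriched]
print(f"\n{len(enriched)} term(s) enriched at alpha=0.1 (uncorrected):")
for r in enriched:
    print(f"  {r.term_id}  {r.name}  p={r.p_value:.3f}  (k={r.study_count}/{r.study_size} "
          f"vs K={r.population_count}/{r.population_size})")
print("\nThe structural-constituent term annotates 14 of the 16 positive-group")
print("instances but only 79 of 116 cohort-wide, so it is mutated relatively")
print("more often in the event-positive patients.")
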