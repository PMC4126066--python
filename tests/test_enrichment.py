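"""Hypergeometric tail, frequency construction, correction, orchestration."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutenrich import (
    AnalysisConfig,
    EnrichmentResult,
    TermFrequencyRecord,
    candidate_terms,
    correct_pvalues,
    differential_frequencies,
    hypergeometric_tail,
    log_hypergeometric_tail,
    profiling_frequencies,
    results_to_frame,
    run_differential,
    run_profiling,
)
from mutenrich.synthetic import HCM_GENOME_SIZE


def exact_tail(N, K, n, k):
    """Enumeration oracle: exact integer hypergeometric upper tail."""
    if k <= 0:
        return 1.0
    total = math.comb(N, n)
    s = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(n, K) + 1))
    return float(Fraction(s, total))


class TestRecordInvariants:
    @pytest.mark.parametrize(
        "k,n,K,N",
        [(5, 4, 10, 20), (2, 4, 1, 20), (2, 21, 10, 20), (-1, 4, 10, 20)],
        ids=["k>n", "k>K", "n>N", "k<0"],
    )
    def test_violations_rejected(self, k, n, K, N):
        with pytest.raises(ValueError):
            TermFrequencyRecord("X:1", k, n, K, N)


class TestHypergeometricTail:
    def test_zero_study_count_gives_one(self):
        assert hypergeometric_tail(TermFrequencyRecord("X:1", 0, 10, 5, 100)) == 1.0

    def test_small_enumeration(self):
        # all 4 draws annotated: C(5,4)/C(10,4) = 5/210
        rec = TermFrequencyRecord("X:1", 4, 4, 5, 10)
        assert hypergeometric_tail(rec) == pytest.approx(5 / 210, rel=1e-12)

    def test_matches_enumeration_on_sampled_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            N = int(rng.integers(1, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            ours = math.exp(log_hypergeometric_tail(N, K, n, k))
            oracle = exact_tail(N, K, n, k)
            assert ours == pytest.approx(oracle, rel=1e-12)

    def test_extreme_tail_no_underflow(self):
        # genome-scale profiling input: p lives around 1e-40, far below
        # double underflow of the naive sum of products
        rec = TermFrequencyRecord("X:1", 15, 16, 550, 18759 * 14)
        p = hypergeometric_tail(rec)
        assert 1e-45 < p < 1e-35

    @given(
        N=st.integers(2, 200),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_k_and_K(self, N, data):
        """p non-increasing in k; non-decreasing in K (fixed everything else)."""
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(1, min(n, K)))
        p = math.exp(log_hypergeometric_tail(N, K, n, k))
        if k > 1:
            assert math.exp(log_hypergeometric_tail(N, K, n, k - 1)) >= p * (1 - 1e-12)
        if K < N and k <= min(n, K + 1):
            assert math.exp(log_hypergeometric_tail(N, K + 1, n, k)) >= p * (1 - 1e-12)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            N = int(rng.integers(1, 1000))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            p = hypergeometric_tail(TermFrequencyRecord("X:1", k, n, K, N))
            assert 0.0 < p <= 1.0


def _result(term, p, ns="biological_process"):
    return EnrichmentResult(term, term, ns, p, p, 1, 10, 5, 100, 0.9, p < 0.1)


class TestCorrectPvalues:
    def test_bonferroni_multiplies_by_test_count(self):
        results = [_result(f"X:{i}", 0.001) for i in range(50)]
        out = correct_pvalues(results, AnalysisConfig())
        assert out[0].p_corrected == pytest.approx(0.05)

    def test_cap_at_one(self):
        results = [_result(f"X:{i}", 0.5) for i in range(10)]
        out = correct_pvalues(results, AnalysisConfig())
        assert out[0].p_corrected == 1.0

    def test_uncapped_exceeds_one(self):
        # 0.026 x 73 tests = 1.9, printed uncapped in report dialects
        results = [_result(f"X:{i:03d}", 0.026) for i in range(73)]
        cfg = AnalysisConfig(cap_corrected_at_one=False)
        out = correct_pvalues(results, cfg)
        assert out[0].p_corrected == pytest.approx(1.9, abs=0.005)

    def test_per_namespace_scope(self):
        results = [_result("X:1", 0.01, "bp"), _result("X:2", 0.01, "bp"), _result("X:3", 0.01, "mf")]
        cfg = AnalysisConfig(bonferroni_scope="per_namespace")
        out = {r.term_id: r for r in correct_pvalues(results, cfg)}
        assert out["X:1"].p_corrected == pytest.approx(0.02)
        assert out["X:3"].p_corrected == pytest.approx(0.01)

    def test_no_tested_terms_is_error(self):
        with pytest.raises(ValueError):
            correct_pvalues([], AnalysisConfig())

    def test_corrected_never_below_raw(self, hcm):
        cohort, graph, index = hcm
        for r in run_differential(cohort, "negative", graph, index):
            assert r.p_corrected >= r.p_value


class TestCandidateTerms:
    def test_unannotated_study_genes_give_empty_set(self, chain_index):
        with pytest.warns(UserWarning, match="no study gene"):
            assert candidate_terms(chain_index, {"nope"}) == frozenset()

    def test_chain_closure_intersected_with_informative(self, chain_index):
        terms = candidate_terms(chain_index, {"geneA"}, informative=frozenset({"T:0003"}))
        assert terms == {"T:0003"}

    def test_union_matches_brute_force(self, hcm):
        cohort, graph, index = hcm
        genes = {"MYBPC3", "MYH7", "CSRP3", "TNNT2"}
        expected = set()
        for g in genes:
            expected |= index.terms_for_gene(g)
        assert candidate_terms(index, genes) == expected


class TestProfilingFrequencies:
    def test_hcm_positive_bookkeeping(self, hcm):
        cohort, graph, index = hcm
        recs = profiling_frequencies(cohort, "positive", index, HCM_GENOME_SIZE)
        assert all(r.study_size == 16 for r in recs)
        assert all(r.population_size == 18759 * 14 for r in recs)

    def test_population_count_is_m_times_genome_count(self, hcm):
        cohort, graph, index = hcm
        for r in profiling_frequencies(cohort, "positive", index, HCM_GENOME_SIZE):
            assert r.population_count == 14 * index.genome_term_count(r.term_id)

    def test_term_annotating_three_scd_genes_counts_fifteen(self, hcm):
        # ventricular morphogenesis annotates MYBPC3, MYH7, TNNT2: 4+9+2 = 15
        cohort, graph, index = hcm
        recs = {r.term_id: r for r in profiling_frequencies(cohort, "positive", index, HCM_GENOME_SIZE)}
        rec = recs["GO:0055010"]
        assert rec.study_count == 15
        assert round(100 * rec.study_count / rec.study_size) == 94

    def test_saturating_term_hits_full_study_set(self, hcm):
        # the function root annotates all 7 panel genes -> k = n = 16
        cohort, graph, index = hcm
        recs = {r.term_id: r for r in profiling_frequencies(cohort, "positive", index, HCM_GENOME_SIZE)}
        assert recs["GO:0003674"].study_count == 16

    def test_genome_smaller_than_panel_is_error(self, hcm):
        cohort, graph, index = hcm
        with pytest.raises(ValueError, match="genome_size"):
            profiling_frequencies(cohort, "positive", index, genome_size=3)


class TestDifferentialFrequencies:
    def test_hcm_set_sizes(self, hcm):
        cohort, graph, index = hcm
        pos = differential_frequencies(cohort, "positive", index)
        neg = differential_frequencies(cohort, "negative", index)
        assert all(r.study_size == 16 and r.population_size == 116 for r in pos)
        assert all(r.study_size == 100 and r.population_size == 116 for r in neg)

    def test_saturating_term_has_k_equal_n(self, hcm):
        cohort, graph, index = hcm
        recs = {r.term_id: r for r in differential_frequencies(cohort, "negative", index)}
        root = recs["GO:0003674"]  # function root annotates all 7 panel genes
        assert root.study_count == root.study_size
        assert root.population_count == root.population_size

    def test_whole_cohort_subgroup_warns_degenerate(self, hcm):
        cohort, graph, index = hcm
        with pytest.warns(UserWarning, match="degenerate"):
            differential_frequencies(cohort, "all", index)


class TestRunAnalyses:
    def test_differential_scd_recovers_muscle_term(self, hcm):
        """The structural-constituent term is enriched in the event-positive
        subgroup (k=14 of n=16 vs K=79 of N=116)."""
        cohort, graph, index = hcm
        results = run_differential(cohort, "positive", graph, index)
        by_id = {r.term_id: r for r in results}
        rec = by_id["GO:0008307"]
        assert (rec.study_count, rec.study_size) == (14, 16)
        assert (rec.population_count, rec.population_size) == (79, 116)
        assert rec.p_value == pytest.approx(0.0604, abs=0.0005)
        assert rec.enriched

    def test_subgroup_equal_to_cohort_gives_all_p_one(self, hcm):
        cohort, graph, index = hcm
        with pytest.warns(UserWarning, match="degenerate"):
            results = run_differential(cohort, "all", graph, index)
        assert all(r.p_value == 1.0 for r in results)

    def test_profiling_results_sorted_and_deterministic(self, hcm):
        cohort, graph, index = hcm
        a = run_profiling(cohort, "positive", graph, index, genome_size=HCM_GENOME_SIZE)
        b = run_profiling(cohort, "positive", graph, index, genome_size=HCM_GENOME_SIZE)
        assert a == b
        keys = [(r.p_value, r.term_id) for r in a]
        assert keys == sorted(keys)

    def test_only_informative_terms_tested(self, hcm):
        """Generic background terms (near-zero IC) never enter the test set,
        so the Bonferroni multiplier counts informative terms only."""
        cohort, graph, index = hcm
        tested = {r.term_id for r in run_profiling(cohort, "positive", graph, index,
                                                   genome_size=HCM_GENOME_SIZE)}
        assert "GO:0008150" not in tested  # namespace root
        assert "GO:0005488" not in tested  # generic binding term

    def test_enriched_flag_uses_uncorrected_p(self, hcm):
        cohort, graph, index = hcm
        for r in run_differential(cohort, "positive", graph, index):
            assert r.enriched == (r.p_value < 0.1)

    def test_single_patient_group_study_size(self):
        import io

        from mutenrich import EventRule, build_index, parse_gaf, read_cohort
        from mutenrich.ontology import parse_obo

        from conftest import CHAIN_OBO, gaf_row

        graph = parse_obo(io.StringIO(CHAIN_OBO))
        anns, _ = parse_gaf(io.StringIO("\n".join(
            [gaf_row("GENE1", "T:0003"), gaf_row("GENE2", "T:0002")])))
        index = build_index(anns, graph)
        tsv = io.StringIO("patient_id\tsd\tGENE1\tGENE2\np1\t1\t1\t0\np2\t0\t0\t1\n")
        cohort = read_cohort(tsv, ["GENE1", "GENE2"], EventRule(positive_if_any=("sd",)))
        recs = profiling_frequencies(cohort, "positive", index, genome_size=10)
        assert all(r.study_size == 1 for r in recs)


class TestResultsFrame:
    def test_fixed_column_order(self, hcm):
        cohort, graph, index = hcm
        frame = results_to_frame(run_differential(cohort, "positive", graph, index))
        assert list(frame.columns) == [
            "term_id", "name", "namespace", "p_value", "p_bonferroni", "k", "n",
            "sfreq_pct", "K", "N", "pfreq_pct", "ic_normalized", "enriched",
        ]

    def test_report_style_formats(self, hcm):
        cohort, graph, index = hcm
        frame = results_to_frame(
            run_profiling(cohort, "positive", graph, index, genome_size=HCM_GENOME_SIZE),
            report_style=True,
        )
        row = frame.set_index("term_id").loc["GO:0055010"]
        assert row["sfreq_pct"] == "94%"
        assert "E-" in row["p_value"]
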