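"""Enrichment: contingency reconstruction, AF ratio, Fisher exact test, Bonferroni."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from varscreen import (
    ContingencyTable,
    FilterConfig,
    ValidationError,
    af_ratio,
    bonferroni_adjust,
    build_contingency,
    compute_frequencies,
    fisher_exact_two_sided,
    format_sigfig,
    round_sigfig,
    run_enrichment,
)
from varscreen.simulate import (
    demo_config,
    make_annotations,
    make_panel_tables,
    simulate_cohort,
)

from _oracles import fisher_oracle


class TestBuildContingency:
    def test_panel_count_reconstructed_half_up(self):
        ct = build_contingency(5, 2152, 1.8e-5, 100_000)  # 1.8 rounds up to 2
        assert (ct.a, ct.b, ct.c, ct.d) == (5, 2147, 2, 99_998)

    def test_absent_in_panel_gives_zero_count(self):
        ct = build_contingency(3, 100, 0.0, 1_000)
        assert (ct.c, ct.d) == (0, 1_000)

    def test_saturated_panel(self):
        ct = build_contingency(1, 10, 1.0, 10)
        assert (ct.c, ct.d) == (10, 0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(1, -1, 0, 5)


class TestAfRatio:
    def test_reference_values_print_at_two_sigfigs(self):
        assert format_sigfig(af_ratio(0.0023, 1.80e-5)) == "130"
        assert format_sigfig(af_ratio(0.012, 5.40e-5)) == "220"

    def test_equal_frequencies_give_unity(self):
        assert af_ratio(0.004, 0.004) == pytest.approx(1.0)

    def test_zero_panel_frequency_undefined(self):
        with pytest.raises(ValidationError):
            af_ratio(0.01, 0.0)

    @given(
        af1=st.floats(1e-6, 1.0), af2=st.floats(1e-6, 1.0), k=st.floats(1e-3, 1e3)
    )
    def test_scale_free(self, af1, af2, k):
        assert af_ratio(af1 * k, af2 * k) == pytest.approx(af_ratio(af1, af2), rel=1e-9)

    def test_round_sigfig_half_up(self):
        assert round_sigfig(125.0, 2) == 130.0
        assert round_sigfig(0.00232, 2) == 0.0023


class TestFisherExact:
    def test_no_signal_table_gives_one(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 10, 0, 10)) == 1.0

    def test_hand_enumerated_table(self):
        # margins (10, 10, k=3): weights 120,450,450,120 over denominator 1140;
        # two-sided mass at a=3 is (120+120)/1140.
        p = fisher_exact_two_sided(ContingencyTable(3, 7, 0, 10))
        assert p == pytest.approx(240 / 1140, abs=1e-12)

    @pytest.mark.parametrize(
        "table",
        [(5, 2147, 2, 99_998), (3, 7, 0, 10), (12, 8, 2, 18), (1, 0, 0, 1), (40, 20, 10, 50)],
    )
    def test_agrees_with_scipy(self, table):
        ours = fisher_exact_two_sided(ContingencyTable(*table))
        theirs = scipy_fisher([[table[0], table[1]], [table[2], table[3]]]).pvalue
        assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)

    def test_one_sided_greater_le_two_sided_for_enriched(self):
        ct = ContingencyTable(12, 8, 2, 18)
        assert fisher_exact_two_sided(ct, alternative="greater") <= fisher_exact_two_sided(ct)

    def test_large_margins_stable(self):
        # panel AN ~ 1e5: log-factorial accumulation must not over/underflow
        p = fisher_exact_two_sided(ContingencyTable(26, 2126, 5, 99_995))
        assert 0.0 < p < 1e-30

    @given(
        r1=st.integers(1, 60), r2=st.integers(1, 60), data=st.data()
    )
    @settings(max_examples=200)
    def test_matches_enumeration_oracle(self, r1, r2, data):
        a = data.draw(st.integers(0, r1))
        c = data.draw(st.integers(0, r2))
        ours = fisher_exact_two_sided(ContingencyTable(a, r1 - a, c, r2 - c))
        assert ours == pytest.approx(fisher_oracle(a, r1 - a, c, r2 - c), abs=1e-9)

    @given(r1=st.integers(0, 40), r2=st.integers(0, 40), data=st.data())
    def test_transposition_symmetry(self, r1, r2, data):
        a = data.draw(st.integers(0, r1))
        c = data.draw(st.integers(0, r2))
        b, d = r1 - a, r2 - c
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        p_t = fisher_exact_two_sided(ContingencyTable(a, c, b, d))
        assert p == pytest.approx(p_t, rel=1e-9, abs=1e-12)


class TestBonferroni:
    def test_single_test_is_identity(self):
        assert bonferroni_adjust([0.03], alpha=0.05) == [(0.03, True)]

    def test_correction_arithmetic(self):
        [(p_adj, sig)] = bonferroni_adjust([0.001], alpha=0.05, m=100)
        assert p_adj == pytest.approx(0.1) and not sig

    def test_cap_at_one_and_order_preserved(self):
        ps = [0.5, 0.001, 0.02, 0.3]
        adjusted = [p for p, _ in bonferroni_adjust(ps, m=10_000)]
        assert max(adjusted) <= 1.0
        # adjustment is monotone: sorting by raw p sorts the adjusted values
        ranked = [adj for _, adj in sorted(zip(ps, adjusted))]
        assert ranked == sorted(ranked)

    def test_empty_list(self):
        assert bonferroni_adjust([]) == []

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_adjust([1.2])


@pytest.fixture(scope="module")
def demo_run():
    cfg = demo_config(seed=3)
    table = simulate_cohort(cfg)
    freqs = compute_frequencies(table)
    run = run_enrichment(
        freqs,
        make_annotations(cfg),
        make_panel_tables(cfg),
        FilterConfig(),
        panel="NFE",
        source="gnomADe",
    )
    return cfg, run


class TestRunEnrichment:

    def test_injected_enriched_sites_significant(self, demo_run):
        _, run = demo_run
        by_key = {str(r.key): r for r in run.results}
        fancc = by_key["chr9_95126582_C_G"]
        assert fancc.significant and format_sigfig(fancc.or_ratio) == "130"
        assert by_key["chr3_195779189_C_G"].significant  # MUC4-like
        assert by_key["chr17_5132920_G_A"].significant  # USP6-like

    def test_low_and_modifier_impacts_not_tested(self, demo_run):
        _, run = demo_run
        assert all(r.impact in ("HIGH", "MODERATE") for r in run.results)

    def test_cohort_only_sidecar(self, demo_run):
        _, run = demo_run
        assert [str(k) for k in run.cohort_only] == ["chr17_43110000_C_G"]

    def test_m_counts_only_tested_variants(self, demo_run):
        _, run = demo_run
        assert run.m == len(run.results)
        for r in run.results:
            assert r.p_bonferroni == pytest.approx(min(1.0, run.m * r.p_value))

    def test_sorted_high_before_moderate_descending_ratio(self, demo_run):
        _, run = demo_run
        order = [(0 if r.impact == "HIGH" else 1, -r.or_ratio) for r in run.results]
        assert order == sorted(order)

    def test_all_benign_low_impact_gives_empty_result(self):
        cfg = demo_config(seed=3)
        table = simulate_cohort(cfg)
        freqs = compute_frequencies(table)
        anns = [a for a in make_annotations(cfg) if a.impact == "LOW"]
        run = run_enrichment(freqs, anns, make_panel_tables(cfg), source="gnomADe")
        assert run.results == [] and run.m == 0

    def test_null_sites_rarely_flagged_across_seeds(self):
        """Family-wise control: no null site flagged, injected always flagged, >=95/100 seeds."""
        clean = 0
        for seed in range(100):
            cfg = demo_config(seed=seed)
            freqs = compute_frequencies(simulate_cohort(cfg))
            run = run_enrichment(
                freqs, make_annotations(cfg), make_panel_tables(cfg), source="gnomADe"
            )
            flagged = {r.gene for r in run.results if r.significant}
            injected_found = {"FANCC", "MUC4", "USP6"} <= flagged
            no_null = flagged <= {"FANCC", "MUC4", "USP6"}
            clean += injected_found and no_null
        assert clean >= 95
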