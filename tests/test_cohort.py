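"""Cohort statistics: frequencies, carriers, combined-set AF, landscape summary."""
import math

import numpy as np
import pytest

from varscreen import (
    FilterConfig,
    ValidationError,
    VariantProfile,
    carrier_prevalence,
    combined_set_af,
    compute_frequencies,
    format_pct,
    landscape_summary,
)

from conftest import make_keys, table_from_dosages


def cohort_with_acs(acs, n_samples=1076):
    """Complete-genotype cohort; row i has AC = acs[i] spread as het carriers."""
    dosages = np.zeros((len(acs), n_samples), dtype=np.int16)
    for i, ac in enumerate(acs):
        n_hom, n_het = divmod(ac, 2) if ac > n_samples else (0, 0)
        if ac <= n_samples:
            dosages[i, :ac] = 1
        else:
            dosages[i, :n_hom] = 2
            dosages[i, n_hom : n_hom + n_het] = 1
    return table_from_dosages(dosages)


class TestComputeFrequencies:
    def test_nine_alleles_in_1076_diploids_prints_042_percent(self):
        (freq,) = compute_frequencies(cohort_with_acs([9]))
        assert freq.ac == 9 and freq.an == 2152
        assert freq.af == pytest.approx(9 / 2152)
        assert format_pct(freq.af) == "0.42"

    def test_singleton_is_rare(self):
        (freq,) = compute_frequencies(cohort_with_acs([1]))
        assert freq.singleton and freq.freq_class == "RARE"

    def test_fixed_site_has_zero_maf(self):
        dosages = np.full((1, 1076), 2, dtype=np.int16)
        (freq,) = compute_frequencies(table_from_dosages(dosages))
        assert freq.af == 1.0 and freq.maf == 0.0 and freq.freq_class == "RARE"

    def test_all_missing_variant_dropped_with_warning(self, caplog):
        dosages = np.array([[-1, -1, -1], [0, 1, 0]], dtype=np.int16)
        with caplog.at_level("WARNING"):
            freqs = compute_frequencies(table_from_dosages(dosages))
        assert len(freqs) == 1 and freqs[0].ac == 1

    def test_rare_common_split_uses_maf_not_af(self):
        # AF 0.995 has MAF 0.005 < 0.01 -> RARE even though AF is high.
        n = 1000
        dosages = np.full((1, n), 2, dtype=np.int16)
        dosages[0, :10] = 1
        (freq,) = compute_frequencies(table_from_dosages(dosages))
        assert freq.af > 0.99 and freq.freq_class == "RARE"


class TestCarrierPrevalence:
    def test_nine_distinct_het_carriers(self):
        table = cohort_with_acs([5, 4])
        # rows share the first samples; build disjoint carriers instead
        dosages = np.zeros((2, 1076), dtype=np.int16)
        dosages[0, :5] = 1
        dosages[1, 5:9] = 1
        table = table_from_dosages(dosages)
        n, prev = carrier_prevalence(table, table.variants)
        assert (n, prev) == (9, 9 / 1076)

    def test_no_carriers(self):
        table = table_from_dosages(np.zeros((2, 10), dtype=np.int16))
        assert carrier_prevalence(table, table.variants) == (0, 0.0)

    def test_sample_with_two_set_variants_counts_once(self):
        dosages = np.zeros((2, 10), dtype=np.int16)
        dosages[0, 0] = 1
        dosages[1, 0] = 1
        table = table_from_dosages(dosages)
        assert carrier_prevalence(table, table.variants) == (1, 0.1)

    def test_homozygote_counts_once(self):
        dosages = np.zeros((1, 10), dtype=np.int16)
        dosages[0, 3] = 2
        table = table_from_dosages(dosages)
        assert carrier_prevalence(table, table.variants) == (1, 0.1)

    def test_absent_key_named_in_error(self):
        table = table_from_dosages(np.zeros((1, 4), dtype=np.int16))
        missing = make_keys(1, chrom="chr9")[0]
        with pytest.raises(KeyError, match=str(missing)):
            carrier_prevalence(table, [missing])

    def test_empty_set_rejected(self):
        table = table_from_dosages(np.zeros((1, 4), dtype=np.int16))
        with pytest.raises(ValidationError):
            carrier_prevalence(table, [])


class TestCombinedSetAf:
    def test_nine_alleles_round_to_042_percent(self):
        table = cohort_with_acs([5, 4])
        af = combined_set_af(table, table.variants)
        assert af == pytest.approx(9 / 2152)
        assert format_pct(af) == "0.42"

    def test_five_alleles_round_to_023_percent(self):
        table = cohort_with_acs([2, 2, 1])
        af = combined_set_af(table, table.variants)
        assert af == pytest.approx(5 / 2152)
        assert format_pct(af) == "0.23"

    def test_single_variant_set_reduces_to_its_af(self):
        table = cohort_with_acs([7, 3])
        (f0, _) = compute_frequencies(table)
        assert combined_set_af(table, [table.variants[0]]) == pytest.approx(f0.af)

    def test_partition_recombines_by_allele_count(self):
        table = cohort_with_acs([5, 4, 3, 2])
        whole = combined_set_af(table, table.variants)
        parts = [table.variants[:2], table.variants[2:]]
        # with a shared allele pool, the set AF is additive over a partition
        recombined = sum(combined_set_af(table, part) for part in parts)
        assert whole == pytest.approx(recombined)

    def test_diploid_carrier_bounds(self):
        rng = np.random.default_rng(11)
        dosages = rng.integers(0, 3, size=(6, 50)).astype(np.int16)
        table = table_from_dosages(dosages)
        total_ac = int(table.ac.sum())
        n_carriers, _ = carrier_prevalence(table, table.variants)
        assert n_carriers <= total_ac
        assert n_carriers >= math.ceil(total_ac / (2 * len(table.variants)))


class TestLandscapeSummary:
    def _profiles(self, table, impacts, regions):
        freqs = compute_frequencies(table)
        return [
            VariantProfile(freq=f, impact=i, region=r)
            for f, i, r in zip(freqs, impacts, regions)
        ]

    def test_counts_match_hand_tally(self):
        acs = [1, 1, 1, 2, 5, 30, 400, 1000, 2000, 1]
        table = cohort_with_acs(acs)
        impacts = ["HIGH"] * 2 + ["MODERATE"] * 3 + ["LOW"] * 2 + ["MODIFIER"] * 3
        regions = ["EXONIC"] * 6 + ["INTRONIC"] * 3 + ["OTHER"]
        summary = landscape_summary(self._profiles(table, impacts, regions))
        assert summary.n_variants == 10
        assert summary.counts_by_impact == {"HIGH": 2, "MODERATE": 3, "LOW": 2, "MODIFIER": 3}
        assert summary.counts_by_region == {"EXONIC": 6, "INTRONIC": 3, "OTHER": 1}
        # rare: maf < 0.01 -> ac <= 21 among AN 2152 (and the fixed-ish 2000 row has maf 0.07...)
        assert summary.n_rare == 6 and summary.n_common == 4
        assert summary.n_singletons == 4
        assert summary.singleton_fraction_of_rare == pytest.approx(4 / 6)
        assert summary.n_rare + summary.n_common == summary.n_variants
        assert sum(summary.counts_by_impact.values()) == summary.n_variants

    def test_empty_input_reports_na_fraction(self):
        summary = landscape_summary([])
        assert summary.n_variants == 0
        assert summary.singleton_fraction_of_rare is None

    def test_singleton_fraction_formats_as_7587(self):
        assert format_pct(9739 / 12836) == "75.87"


class TestConfig:
    def test_defaults(self):
        cfg = FilterConfig()
        assert (cfg.maf_rare_threshold, cfg.cadd_threshold, cfg.padding_bp, cfg.alpha) == (
            0.01, 20.0, 10_000, 0.05,
        )

    @pytest.mark.parametrize(
        "kwargs", [{"maf_rare_threshold": 0}, {"alpha": 0.0}, {"alpha": 1.0}, {"cadd_threshold": -1}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            FilterConfig(**kwargs)

    def test_yaml_and_override_precedence(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("maf_rare_threshold: 0.05\nalpha: 0.01\n")
        cfg = FilterConfig.from_yaml(p).merged(alpha=0.02, padding_bp=None)
        assert cfg.maf_rare_threshold == 0.05
        assert cfg.alpha == 0.02
        assert cfg.padding_bp == 10_000
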