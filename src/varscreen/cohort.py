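"""Cohort-level variant statistics.

Per-variant allele frequency (AF = AC/AN), minor allele frequency, the
rare/common split (rare = MAF below the configured threshold, default 0.01),
singleton status (AC = 1), carrier prevalence of a variant set (fraction of
individuals with at least one alternate allele at any set member), the
combined allele frequency of a variant set, and the landscape summary
(counts by impact and region, singleton fraction among rare variants).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .config import FilterConfig
from .errors import ValidationError
from .io import CohortGenotypeTable, VariantKey

logger = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(fraction: float, decimals: int = 2) -> str:
    """Render a fraction as a percentage string, half-up (0.0041821 → ``'0.42'``)."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(fraction) * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VariantFrequency:
    """Cohort frequency summary for one monoallelic variant."""

    key: VariantKey
    ac: int
    an: int
    af: float
    maf: float
    freq_class: str  # RARE | COMMON
    singleton: bool


def compute_frequencies(
    table: CohortGenotypeTable, config: FilterConfig | None = None
) -> list[VariantFrequency]:
    """Per-variant AF/MAF/rarity/singleton status from recomputed AC and AN.

    Variants with AN = 0 (all genotypes missing) are dropped with a warning.
    """
    config = config or FilterConfig()
    acs = table.ac
    ans = table.an
    out: list[VariantFrequency] = []
    n_dropped = 0
    for key, ac, an in zip(table.variants, acs, ans):
        ac, an = int(ac), int(an)
        if an == 0:
            n_dropped += 1
            continue
        af = ac / an
        maf = min(af, 1.0 - af)
        out.append(
            VariantFrequency(
                key=key,
                ac=ac,
                an=an,
                af=af,
                maf=maf,
                freq_class="RARE" if maf < config.maf_rare_threshold else "COMMON",
                singleton=(ac == 1),
            )
        )
    if n_dropped:
        logger.warning("compute_frequencies: dropped %d variant(s) with AN = 0", n_dropped)
    return out


def carrier_prevalence(
    table: CohortGenotypeTable, variant_set: Iterable[VariantKey]
) -> tuple[int, float]:
    """Number and fraction of samples carrying ≥ 1 alt allele at any set variant.

    A sample carrying several set variants (or a homozygote) counts once.
    """
    keys = list(variant_set)
    if not keys:
        raise ValidationError("carrier_prevalence requires a non-empty variant set")
    idx = [table.index_of(k) for k in keys]
    carriers = (table.dosages[idx] >= 1).any(axis=0)
    n_carriers = int(carriers.sum())
    return n_carriers, n_carriers / table.n_samples


def combined_set_af(
    table: CohortGenotypeTable, variant_set: Iterable[VariantKey]
) -> float:
    """Combined allele frequency of a variant set: total alt alleles over the
    cohort allele pool.

    When every set variant shares the same AN (the usual complete-genotype
    case) this is Σ AC / AN; with per-variant missingness the allele pool is
    taken as the mean AN over the set.
    """
    keys = list(variant_set)
    if not keys:
        raise ValidationError("combined_set_af requires a non-empty variant set")
    idx = [table.index_of(k) for k in keys]
    ans = table.an[idx]
    if np.any(ans == 0):
        raise ValidationError("combined_set_af: a set variant has AN = 0")
    total_ac = int(table.ac[idx].sum())
    return total_ac / float(ans.mean())


@dataclass(frozen=True)
class VariantProfile:
    """A frequency record joined with its impact and region classes."""

    freq: VariantFrequency
    impact: str
    region: str


@dataclass(frozen=True)
class CohortSummary:
    """Landscape of a screened variant set."""

    n_variants: int
    counts_by_impact: dict[str, int]
    counts_by_region: dict[str, int]
    n_rare: int
    n_common: int
    n_singletons: int
    singleton_fraction_of_rare: float | None  # None when no rare variants


def landscape_summary(profiles: Sequence[VariantProfile]) -> CohortSummary:
    """Tally variants by impact, region and frequency class.

    ``singleton_fraction_of_rare`` is the share of rare variants seen on a
    single allele; it is None (reported as NA) for an empty rare set.
    """
    counts_by_impact: dict[str, int] = {}
    counts_by_region: dict[str, int] = {}
    n_rare = n_common = n_singletons = 0
    n_singleton_rare = 0
    for p in profiles:
        counts_by_impact[p.impact] = counts_by_impact.get(p.impact, 0) + 1
        counts_by_region[p.region] = counts_by_region.get(p.region, 0) + 1
        if p.freq.freq_class == "RARE":
            n_rare += 1
            if p.freq.singleton:
                n_singleton_rare += 1
        else:
            n_common += 1
        if p.freq.singleton:
            n_singletons += 1
    fraction = (n_singleton_rare / n_rare) if n_rare else None
    return CohortSummary(
        n_variants=len(profiles),
        counts_by_impact=counts_by_impact,
        counts_by_region=counts_by_region,
        n_rare=n_rare,
        n_common=n_common,
        n_singletons=n_singletons,
        singleton_fraction_of_rare=fraction,
    )
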