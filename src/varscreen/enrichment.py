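"""Cohort-vs-reference allele-frequency enrichment.

The enrichment statistic is the allele-frequency ratio AF_cohort / AF_panel.
It is conventionally reported under the name "OR" in this kind of screen, but
it is a ratio of allele frequencies, not a true odds ratio; the report column
is therefore named ``af_ratio_or``. Significance comes from Fisher's exact
test on a 2×2 table of allele counts (cohort alt/ref vs panel alt/ref, the
panel's alt count reconstructed as round-half-up(AF × AN)), followed by
Bonferroni correction over the variants actually tested.

The two-sided p-value uses the minimum-likelihood definition: the sum of
point hypergeometric probabilities not exceeding that of the observed table
(relative tolerance 1e-7 on the comparison), accumulated from a log-factorial
table for stability at panel allele numbers around 1e5.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Context
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .classify import AnnotationRecord
from .cohort import VariantFrequency
from .config import FilterConfig
from .errors import ValidationError
from .io import VariantKey
from .sharing import PanelFrequency

logger = logging.getLogger(__name__)

_REL_TOL = 1e-7
_LOG_GATE = math.log1p(_REL_TOL)

# Log-factorial cache, grown geometrically on demand.
_LFACT = gammaln(np.arange(2, dtype=np.float64) + 1.0)


def _lfact(n_max: int) -> np.ndarray:
    global _LFACT
    if n_max >= _LFACT.size:
        size = max(n_max + 1, 2 * _LFACT.size)
        _LFACT = gammaln(np.arange(size, dtype=np.float64) + 1.0)
    return _LFACT


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 allele-count table: cohort (a alt, b ref) vs panel (c alt, d ref)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"negative cell in contingency table {self}")


def round_sigfig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half-up (127.8 → 130.0)."""
    if x == 0:
        return 0.0
    ctx = Context(prec=sig, rounding=ROUND_HALF_UP)
    return float(ctx.create_decimal(repr(float(x))))


def format_sigfig(x: float, sig: int = 2) -> str:
    """Significant-figure string without exponent notation for moderate magnitudes."""
    return f"{round_sigfig(x, sig):g}"


def build_contingency(ac: int, an: int, panel_af: float, panel_an: int) -> ContingencyTable:
    """Reconstruct the allele-count table; panel alt count = round-half-up(AF × AN)."""
    if an <= 0 or panel_an <= 0:
        raise ValidationError("both allele numbers must be positive")
    if not (0.0 <= panel_af <= 1.0):
        raise ValidationError(f"panel AF {panel_af} outside [0, 1]")
    if ac < 0 or ac > an:
        raise ValidationError(f"cohort AC {ac} outside [0, AN={an}]")
    c = math.floor(panel_af * panel_an + 0.5)
    if c > panel_an:
        raise ValidationError(f"reconstructed panel AC {c} exceeds panel AN {panel_an}")
    return ContingencyTable(a=ac, b=an - ac, c=c, d=panel_an - c)


def af_ratio(af_cohort: float, af_panel: float) -> float:
    """The enrichment statistic AF_cohort / AF_panel (undefined at AF_panel = 0)."""
    if af_panel <= 0:
        raise ValidationError("af_ratio undefined for panel AF <= 0; variant is cohort-only")
    return af_cohort / af_panel


def _log_pmf_support(r1: int, r2: int, k: int) -> tuple[int, np.ndarray]:
    """Hypergeometric log-pmf over the support of the first cell, via log-factorials."""
    n = r1 + r2
    lf = _lfact(n)
    lo = max(0, k - r2)
    hi = min(k, r1)
    x = np.arange(lo, hi + 1)
    log_pmf = (
        lf[r1] - lf[x] - lf[r1 - x]
        + lf[r2] - lf[k - x] - lf[r2 - (k - x)]
        - (lf[n] - lf[k] - lf[n - k])
    )
    return lo, log_pmf


def fisher_exact_two_sided(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Fisher's exact test on a 2×2 allele-count table.

    ``two-sided`` sums all tables with the observed margins whose point
    probability is at most that of the observed table (within a 1e-7 relative
    gate); ``greater``/``less`` are one-sided on the cohort alt count.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0  # degenerate margins: only one table possible
    lo, log_pmf = _log_pmf_support(r1, r2, k)
    obs = log_pmf[a - lo]
    if alternative == "two-sided":
        mask = log_pmf <= obs + _LOG_GATE
    elif alternative == "greater":
        mask = np.arange(lo, lo + log_pmf.size) >= a
    elif alternative == "less":
        mask = np.arange(lo, lo + log_pmf.size) <= a
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float(np.exp(log_pmf[mask]).sum())
    return min(1.0, p)


def bonferroni_adjust(
    p_values: Sequence[float], alpha: float = 0.05, m: int | None = None
) -> list[tuple[float, bool]]:
    """Bonferroni correction: p_adj = min(1, m·p); significant iff p_adj < alpha."""
    if any(not (0.0 <= p <= 1.0) for p in p_values):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p_values) if m is None else m
    return [(min(1.0, m * p), min(1.0, m * p) < alpha) for p in p_values]


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment outcome for one variant against one reference panel."""

    key: VariantKey
    gene: str | None
    impact: str
    cadd: float | None
    af_cohort: float
    af_panel: float
    or_ratio: float
    p_value: float
    p_bonferroni: float
    significant: bool


@dataclass(frozen=True)
class EnrichmentRun:
    """Full enrichment output: tested results, cohort-only variants, test count."""

    results: list[EnrichmentResult]
    cohort_only: list[VariantKey]
    m: int
    alpha: float


_IMPACT_ORDER = {"HIGH": 0, "MODERATE": 1}


def run_enrichment(
    frequencies: Iterable[VariantFrequency],
    annotations: Iterable[AnnotationRecord] | Mapping[VariantKey, AnnotationRecord],
    panels: Iterable[PanelFrequency],
    config: FilterConfig | None = None,
    panel: str = "NFE",
    source: str | None = None,
    alternative: str = "two-sided",
) -> EnrichmentRun:
    """Screen cohort variants for frequency enrichment against one reference panel.

    Pipeline order: (1) keep HIGH/MODERATE-impact variants; (2) keep variants
    present in the panel table with AF > 0 (the rest go to the cohort-only
    list); (3) AF ratio + Fisher exact test on reconstructed allele counts;
    (4) Bonferroni over the number of variants actually tested. Results are
    ordered HIGH before MODERATE, descending ratio within each class.
    """
    config = config or FilterConfig()
    if isinstance(annotations, Mapping):
        ann_by_key = dict(annotations)
    else:
        ann_by_key = {rec.key: rec for rec in annotations}

    panel_by_key: dict[VariantKey, PanelFrequency] = {}
    for p in panels:
        if p.panel != panel or (source is not None and p.source != source):
            continue
        if p.key in panel_by_key and (p.af, p.an) != (panel_by_key[p.key].af, panel_by_key[p.key].an):
            raise ValidationError(
                f"conflicting {panel} records for {p.key} across sources; pass source="
            )
        panel_by_key[p.key] = p

    candidates = []
    n_unannotated = 0
    for freq in frequencies:
        rec = ann_by_key.get(freq.key)
        if rec is None:
            n_unannotated += 1
            continue
        if rec.impact in _IMPACT_ORDER:
            candidates.append((freq, rec))
    if n_unannotated:
        logger.warning("run_enrichment: %d variant(s) lacked annotation and were skipped", n_unannotated)

    tested: list[tuple[VariantFrequency, AnnotationRecord, PanelFrequency]] = []
    cohort_only: list[VariantKey] = []
    for freq, rec in candidates:
        pf = panel_by_key.get(freq.key)
        if pf is None or pf.af <= 0.0:
            cohort_only.append(freq.key)
        else:
            tested.append((freq, rec, pf))

    if not tested:
        logger.warning("run_enrichment: no variants survived the impact/panel filters")

    raw: list[tuple[VariantFrequency, AnnotationRecord, PanelFrequency, float, float]] = []
    for freq, rec, pf in tested:
        ratio = af_ratio(freq.af, pf.af)
        ct = build_contingency(freq.ac, freq.an, pf.af, pf.an)
        p = fisher_exact_two_sided(ct, alternative=alternative)
        raw.append((freq, rec, pf, ratio, p))

    m = len(raw)
    adjusted = bonferroni_adjust([r[4] for r in raw], alpha=config.alpha, m=m) if raw else []
    results = [
        EnrichmentResult(
            key=freq.key,
            gene=rec.gene,
            impact=rec.impact,
            cadd=rec.cadd,
            af_cohort=freq.af,
            af_panel=pf.af,
            or_ratio=ratio,
            p_value=p,
            p_bonferroni=p_adj,
            significant=sig,
        )
        for (freq, rec, pf, ratio, p), (p_adj, sig) in zip(raw, adjusted)
    ]
    results.sort(key=lambda r: (_IMPACT_ORDER[r.impact], -r.or_ratio, str(r.key)))
    cohort_only.sort(key=lambda k: k.sort_tuple())
    return EnrichmentRun(results=results, cohort_only=cohort_only, m=m, alpha=config.alpha)
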