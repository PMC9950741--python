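"""Seeded synthetic cohorts and reference-panel tables.

The generator emulates the statistical structure the screening pipeline
assumes: a diploid cohort (default 1076 individuals) whose per-site
genotypes are drawn under Hardy–Weinberg equilibrium (dosage ~
Binomial(2, AF), independent across sites — no linkage disequilibrium),
plus "founder" sites where an exact number of heterozygous/homozygous
carriers is placed deterministically so that printed-number scenarios
(e.g. nine carriers of a pathogenic set → combined AF 0.42%) reproduce
exactly. Matching gene-interval, annotation and reference-panel tables are
emitted so every pipeline stage is exercisable with no external download.

Randomness is governed by one global seed; each site derives a substream
from a stable hash of its variant key, so adding or removing a site does
not perturb the genotypes of the others.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .classify import AnnotationRecord
from .errors import ValidationError
from .io import (
    CohortGenotypeTable,
    GeneInterval,
    VariantKey,
    write_cohort_vcf,
)
from .sharing import PanelFrequency

__all__ = [
    "SiteSpec",
    "FounderInjection",
    "PanelSpec",
    "GeneSpec",
    "SimulationConfig",
    "simulate_cohort",
    "make_panel_tables",
    "make_annotations",
    "make_gene_intervals",
    "write_fixture_bundle",
    "demo_config",
]


@dataclass(frozen=True)
class SiteSpec:
    """One simulated site: identity, generating AF and annotation payload."""

    key: VariantKey
    generating_af: float = 0.0
    gene: str | None = None
    consequence_terms: tuple[str, ...] = ("intergenic_variant",)
    clin_sig: str = ""
    cadd: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.generating_af <= 1.0):
            raise ValidationError(f"{self.key}: generating_af {self.generating_af} outside [0, 1]")


@dataclass(frozen=True)
class FounderInjection:
    """Exact carrier placement for a founder-like site."""

    key: VariantKey
    n_het: int
    n_hom: int = 0

    def __post_init__(self) -> None:
        if self.n_het < 0 or self.n_hom < 0:
            raise ValidationError(f"{self.key}: negative carrier count")


@dataclass(frozen=True)
class PanelSpec:
    """One reference-panel frequency row to emit."""

    source: str
    panel: str
    key: VariantKey
    af: float
    an: int


@dataclass(frozen=True)
class GeneSpec:
    """Raw (unpadded) gene interval to emit."""

    gene: str
    chrom: str
    start: int
    end: int


@dataclass
class SimulationConfig:
    """Everything needed to generate one reproducible fixture bundle."""

    n_individuals: int = 1076
    sites: list[SiteSpec] = field(default_factory=list)
    founder_injections: list[FounderInjection] = field(default_factory=list)
    panel_specs: list[PanelSpec] = field(default_factory=list)
    gene_intervals: list[GeneSpec] = field(default_factory=list)
    seed: int = 0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValidationError("n_individuals must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must lie in [0, 1)")
        site_keys = {s.key for s in self.sites}
        if len(site_keys) != len(self.sites):
            raise ValidationError("duplicate site keys in simulation config")
        for inj in self.founder_injections:
            if inj.key not in site_keys:
                raise ValidationError(f"founder injection {inj.key} has no matching site spec")
        total_carriers = sum(i.n_het + i.n_hom for i in self.founder_injections)
        if total_carriers > self.n_individuals:
            raise ValidationError(
                f"injected carriers ({total_carriers}) exceed cohort size ({self.n_individuals})"
            )

    def config_hash(self) -> str:
        """Stable SHA-256 of the configuration (keys rendered as strings)."""
        payload = asdict(self)
        for section in ("sites", "founder_injections", "panel_specs"):
            for entry in payload[section]:
                entry["key"] = str(VariantKey(**entry["key"]))
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from YAML (site/injection/panel entries as mappings)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sites = [
            SiteSpec(
                key=VariantKey.parse(s["key"]),
                generating_af=float(s.get("generating_af", 0.0)),
                gene=s.get("gene"),
                consequence_terms=tuple(s.get("consequence_terms", ["intergenic_variant"])),
                clin_sig=s.get("clin_sig", ""),
                cadd=(float(s["cadd"]) if s.get("cadd") is not None else None),
            )
            for s in raw.get("sites", [])
        ]
        injections = [
            FounderInjection(
                key=VariantKey.parse(i["key"]),
                n_het=int(i.get("n_het", 0)),
                n_hom=int(i.get("n_hom", 0)),
            )
            for i in raw.get("founder_injections", [])
        ]
        panels = [
            PanelSpec(
                source=p.get("source", "default"),
                panel=p["panel"],
                key=VariantKey.parse(p["key"]),
                af=float(p["af"]),
                an=int(p["an"]),
            )
            for p in raw.get("panel_specs", [])
        ]
        genes = [
            GeneSpec(g["gene"], g["chrom"], int(g["start"]), int(g["end"]))
            for g in raw.get("gene_intervals", [])
        ]
        return cls(
            n_individuals=int(raw.get("n_individuals", 1076)),
            sites=sites,
            founder_injections=injections,
            panel_specs=panels,
            gene_intervals=genes,
            seed=int(raw.get("seed", 0)),
            missing_rate=float(raw.get("missing_rate", 0.0)),
        )


def _site_rng(seed: int, key: VariantKey) -> np.random.Generator:
    """Per-site substream: stable hash of the variant key mixed with the seed."""
    digest = hashlib.sha256(str(key).encode()).digest()
    site_word = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, site_word]))


def simulate_cohort(config: SimulationConfig) -> CohortGenotypeTable:
    """Draw a diploid cohort genotype table from the configuration.

    Non-injected sites: per-individual dosage ~ Binomial(2, generating_af)
    (Hardy–Weinberg). Injected sites: exactly the requested het/hom carriers,
    placed in individuals disjoint across all injected sites (so printed
    carrier counts are deterministic), dosage 0 elsewhere and no missingness.
    Fully reproducible from ``config.seed``.
    """
    n = config.n_individuals
    injected = {inj.key: inj for inj in config.founder_injections}

    # Disjoint carrier placement across all founder sites, from one permutation.
    placement_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0xF0CDE])
    )
    permutation = placement_rng.permutation(n)
    cursor = 0

    sites = sorted(config.sites, key=lambda s: s.key.sort_tuple())
    dosages = np.zeros((len(sites), n), dtype=np.int16)
    called = np.full((len(sites), n), 2, dtype=np.int16)

    for row, site in enumerate(sites):
        inj = injected.get(site.key)
        if inj is not None:
            homs = permutation[cursor : cursor + inj.n_hom]
            cursor += inj.n_hom
            hets = permutation[cursor : cursor + inj.n_het]
            cursor += inj.n_het
            dosages[row, homs] = 2
            dosages[row, hets] = 1
            continue
        rng = _site_rng(config.seed, site.key)
        if site.generating_af > 0.0:
            dosages[row] = rng.binomial(2, site.generating_af, size=n)
        if config.missing_rate > 0.0:
            mask = rng.random(n) < config.missing_rate
            dosages[row, mask] = 0
            called[row, mask] = 0

    sample_ids = [f"S{i:04d}" for i in range(n)]
    return CohortGenotypeTable([s.key for s in sites], dosages, called, sample_ids)


def make_panel_tables(config: SimulationConfig) -> list[PanelFrequency]:
    """Materialize the configured reference-panel rows."""
    return [
        PanelFrequency(source=p.source, panel=p.panel, key=p.key, af=p.af, an=p.an)
        for p in config.panel_specs
    ]


def make_annotations(config: SimulationConfig) -> list[AnnotationRecord]:
    """Annotation records for every configured site."""
    return [
        AnnotationRecord(
            key=s.key,
            gene=s.gene,
            consequence_terms=list(s.consequence_terms),
            clin_sig=s.clin_sig,
            cadd=s.cadd,
        )
        for s in sorted(config.sites, key=lambda s: s.key.sort_tuple())
    ]


def make_gene_intervals(config: SimulationConfig, padding: int = 10_000) -> list[GeneInterval]:
    """Padded gene intervals for the configured loci."""
    return [
        GeneInterval.from_raw(g.gene, g.chrom, g.start, g.end, padding)
        for g in config.gene_intervals
    ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(config: SimulationConfig, directory: str | Path) -> dict[str, Path]:
    """Write cohort VCF, gene/annotation/panel TSVs and a manifest to ``directory``.

    The manifest records the seed, a hash of the config, per-file SHA-256
    checksums and a truth block (injected ACs and generating AFs) so tests
    can check parameter recovery against what was actually simulated.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table = simulate_cohort(config)

    paths = {
        "vcf": directory / "cohort.vcf",
        "genes": directory / "genes.tsv",
        "annotations": directory / "annotations.tsv",
        "panels": directory / "panels.tsv",
        "manifest": directory / "manifest.json",
    }

    write_cohort_vcf(table, paths["vcf"])

    with open(paths["genes"], "w") as fh:
        fh.write("gene\tchrom\tstart\tend\n")
        for g in sorted(config.gene_intervals, key=lambda g: (g.chrom, g.start, g.gene)):
            fh.write(f"{g.gene}\t{g.chrom}\t{g.start}\t{g.end}\n")

    with open(paths["annotations"], "w") as fh:
        fh.write("variant_key\tgene\tconsequence_terms\tclin_sig\tcadd\n")
        for s in sorted(config.sites, key=lambda s: s.key.sort_tuple()):
            cadd = "" if s.cadd is None else repr(s.cadd)
            fh.write(
                f"{s.key}\t{s.gene or ''}\t{','.join(s.consequence_terms)}\t{s.clin_sig}\t{cadd}\n"
            )

    with open(paths["panels"], "w") as fh:
        fh.write("source\tpanel\tvariant_key\taf\tan\n")
        for p in sorted(
            config.panel_specs, key=lambda p: (p.source, p.panel, p.key.sort_tuple())
        ):
            fh.write(f"{p.source}\t{p.panel}\t{p.key}\t{p.af!r}\t{p.an}\n")

    injected = {inj.key: inj for inj in config.founder_injections}
    truth = {}
    for s in sorted(config.sites, key=lambda s: s.key.sort_tuple()):
        inj = injected.get(s.key)
        truth[str(s.key)] = {
            "generating_af": s.generating_af,
            "injected_ac": (inj.n_het + 2 * inj.n_hom) if inj else None,
            "injected_carriers": (inj.n_het + inj.n_hom) if inj else None,
        }

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_individuals": config.n_individuals,
        "files": {name: _sha256(p) for name, p in paths.items() if name != "manifest"},
        "truth": truth,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# Demo scenario
# ---------------------------------------------------------------------------

# Seven pathogenic/likely-pathogenic breast-cancer-gene sites. Three are
# BRCA1 founder-like alleles carrying five alt alleles in total (combined AF
# 5/2152 -> 0.23%); four BRCA2 sites add one carrier each, for nine carriers
# and combined AF 9/2152 -> 0.42% in the default 1076-individual cohort.
_BRCA1_FOUNDERS: Sequence[tuple[str, int, str]] = (
    ("chr17_43057062_T_TG", 2, "frameshift_variant"),
    ("chr17_43093299_AAGACT_A", 2, "frameshift_variant"),
    ("chr17_43104967_T_G", 1, "missense_variant"),
)
_BRCA2_PLP: Sequence[tuple[str, int, str]] = (
    ("chr13_32316477_ATG_A", 1, "frameshift_variant"),
    ("chr13_32332592_C_CA", 1, "frameshift_variant"),
    ("chr13_32340301_G_GT", 1, "frameshift_variant"),
    ("chr13_32398489_A_T", 1, "missense_variant"),
)

# Enriched sites mirroring the reproducible reference-ratio scenarios:
# (key, gene, consequence, cadd, injected het carriers, NFE panel af).
_ENRICHED: Sequence[tuple[str, str, str, float, int, float]] = (
    ("chr9_95126582_C_G", "FANCC", "stop_gained", 33.0, 5, 1.8e-05),
    ("chr3_195779189_C_G", "MUC4", "missense_variant", 17.14, 26, 5.4e-05),
    ("chr17_5132920_G_A", "USP6", "missense_variant", 3.634, 5, 1.8e-05),
)

_NFE_PANEL_AN = 100_000


def demo_config(seed: int = 0, n_individuals: int = 1076) -> SimulationConfig:
    """The default demonstration scenario.

    Contents:

    * seven P/LP BRCA1/BRCA2 sites with nine injected heterozygous carriers
      (combined AF 0.42%; the three BRCA1 founder-like sites alone give 0.23%);
    * three reference-enriched sites (FANCC-, MUC4- and USP6-like) whose
      cohort/NFE AF ratios print as 130, 220 and 130 at two significant figures;
    * Hardy–Weinberg null sites with NFE panel AF equal to the generating AF;
    * ancestry panels (gnomADg-like source) built so the seven-variant P/LP set
      is shared 5/7 with NFE, 3/7 AMR, 2/7 AFR, 1/7 EAS, 1/7 SAS, while a
      1KGP-like source contains none of them (all seven cohort-unique) and a
      gnomADe-like source contains all of them.
    """
    sites: list[SiteSpec] = []
    injections: list[FounderInjection] = []
    panels: list[PanelSpec] = []

    genes = [
        GeneSpec("BRCA1", "chr17", 43_044_295, 43_125_364),
        GeneSpec("BRCA2", "chr13", 32_315_086, 32_400_268),
        GeneSpec("FANCC", "chr9", 95_099_055, 95_317_730),
        GeneSpec("MUC4", "chr3", 195_746_765, 195_811_973),
        GeneSpec("USP6", "chr17", 5_129_013, 5_186_209),
    ]

    plp_keys: list[VariantKey] = []
    for key_str, n_het, term in _BRCA1_FOUNDERS:
        key = VariantKey.parse(key_str)
        plp_keys.append(key)
        sites.append(
            SiteSpec(
                key=key,
                gene="BRCA1",
                consequence_terms=(term,),
                clin_sig="Pathogenic",
                cadd=28.0,
            )
        )
        injections.append(FounderInjection(key=key, n_het=n_het))
    for key_str, n_het, term in _BRCA2_PLP:
        key = VariantKey.parse(key_str)
        plp_keys.append(key)
        sites.append(
            SiteSpec(
                key=key,
                gene="BRCA2",
                consequence_terms=(term,),
                clin_sig="Likely_pathogenic",
                cadd=25.0,
            )
        )
        injections.append(FounderInjection(key=key, n_het=n_het))

    for key_str, gene, term, cadd, n_het, nfe_af in _ENRICHED:
        key = VariantKey.parse(key_str)
        sites.append(
            SiteSpec(key=key, gene=gene, consequence_terms=(term,), clin_sig="", cadd=cadd)
        )
        injections.append(FounderInjection(key=key, n_het=n_het))
        panels.append(PanelSpec("gnomADe", "NFE", key, nfe_af, _NFE_PANEL_AN))

    # Null Hardy-Weinberg sites: cohort AF generated at the panel AF.
    null_sites = [
        ("chr17_43070000_G_A", "BRCA1", "missense_variant", 22.0, 0.05),
        ("chr13_32350000_C_T", "BRCA2", "missense_variant", 23.5, 0.2),
        ("chr9_95200000_T_C", "FANCC", "missense_variant", 21.0, 0.005),
        ("chr3_195800000_G_C", "MUC4", "synonymous_variant", 7.1, 0.1),
        ("chr9_95150000_A_G", "FANCC", "intron_variant", 1.2, 0.3),
    ]
    for key_str, gene, term, cadd, af in null_sites:
        key = VariantKey.parse(key_str)
        sites.append(
            SiteSpec(
                key=key,
                generating_af=af,
                gene=gene,
                consequence_terms=(term,),
                clin_sig="Benign" if term == "synonymous_variant" else "",
                cadd=cadd,
            )
        )
        panels.append(PanelSpec("gnomADe", "NFE", key, af, _NFE_PANEL_AN))
        panels.append(PanelSpec("1KGP", "EUR", key, af, 6_404))

    # A rare cohort-only site: moderate impact but absent from every panel.
    cohort_only_key = VariantKey.parse("chr17_43110000_C_G")
    sites.append(
        SiteSpec(
            key=cohort_only_key,
            generating_af=0.0005,
            gene="BRCA1",
            consequence_terms=("missense_variant",),
            clin_sig="Uncertain_significance",
            cadd=24.3,
        )
    )

    # BRCA P/LP sites are present in the gnomADe NFE panel at about their
    # expected cohort frequency, so they are tested but not significant.
    for key, n_het in zip(
        plp_keys, [n for _, n, _ in _BRCA1_FOUNDERS] + [n for _, n, _ in _BRCA2_PLP]
    ):
        panels.append(
            PanelSpec("gnomADe", "NFE", key, n_het / (2 * n_individuals), _NFE_PANEL_AN)
        )

    # gnomADg-like ancestry membership over the seven P/LP variants:
    # NFE 5/7, AMR 3/7, AFR 2/7, EAS 1/7, SAS 1/7.
    f1, f2, f3, b1, b2 = plp_keys[0], plp_keys[1], plp_keys[2], plp_keys[3], plp_keys[4]
    membership = {
        "NFE": [f1, f2, f3, b1, b2],
        "AMR": [f1, f2, b1],
        "AFR": [f1, f2],
        "EAS": [f1],
        "SAS": [f1],
    }
    for panel, members in membership.items():
        for key in members:
            panels.append(PanelSpec("gnomADg", panel, key, 1e-4, 50_000))

    return SimulationConfig(
        n_individuals=n_individuals,
        sites=sites,
        founder_injections=injections,
        panel_specs=panels,
        gene_intervals=genes,
        seed=seed,
    )


def demo_plp_keys() -> list[VariantKey]:
    """The seven P/LP BRCA1/BRCA2 demo keys (founder-like BRCA1 sites first)."""
    return [VariantKey.parse(k) for k, _, _ in _BRCA1_FOUNDERS] + [
        VariantKey.parse(k) for k, _, _ in _BRCA2_PLP
    ]


def demo_founder_keys() -> list[VariantKey]:
    """The three BRCA1 founder-like demo keys (combined AF 0.23% scenario)."""
    return [VariantKey.parse(k) for k, _, _ in _BRCA1_FOUNDERS]
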