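"""Variant classification: gene assignment, impact, pathogenicity, region, CADD.

Impact follows a max-severity rule over Sequence Ontology consequence terms
using a shipped, user-editable term table (``data/so_impact.tsv``); terms not
in the table fall back to MODIFIER. Pathogenicity buckets ClinVar-style
clinical-significance labels into P/LP, VUS, conflicting, benign/likely-benign
or unclassified. The CADD filter keeps variants at or above a PHRED-scaled
deleteriousness threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .errors import ValidationError
from .io import GeneInterval, VariantKey

logger = logging.getLogger(__name__)

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_SEVERITY = {c: i for i, c in enumerate(reversed(IMPACT_CLASSES))}

PATH_CLASSES = ("P_LP", "VUS", "CONFLICTING", "BENIGN_LB", "UNCLASSIFIED")
REGION_CLASSES = ("EXONIC", "INTRONIC", "OTHER")

# Terms whose position lies in transcribed exonic sequence.
EXONIC_TERMS = frozenset(
    {
        "transcript_ablation",
        "stop_gained",
        "stop_lost",
        "stop_retained_variant",
        "start_lost",
        "start_retained_variant",
        "frameshift_variant",
        "missense_variant",
        "synonymous_variant",
        "inframe_insertion",
        "inframe_deletion",
        "protein_altering_variant",
        "coding_sequence_variant",
        "incomplete_terminal_codon_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
    }
)

INTRONIC_TERMS = frozenset(
    {
        "intron_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
        "splice_donor_region_variant",
        "splice_donor_5th_base_variant",
        "splice_polypyrimidine_tract_variant",
    }
)

_P_LP_LABELS = {"pathogenic", "likely_pathogenic", "pathogenic/likely_pathogenic"}
_BENIGN_LABELS = {"benign", "likely_benign", "benign/likely_benign"}


def load_impact_table(path: str | Path | None = None) -> dict[str, str]:
    """Load the SO-term → impact-class table (the shipped default or a custom TSV)."""
    if path is None:
        text = resources.files("varscreen.data").joinpath("so_impact.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, str] = {}
    lines = text.strip().splitlines()
    for line in lines[1:]:  # skip header
        term, impact = line.rstrip("\n").split("\t")
        if impact not in IMPACT_CLASSES:
            raise ValidationError(f"unknown impact class {impact!r} for term {term!r}")
        table[term] = impact
    return table


_DEFAULT_IMPACT_TABLE = load_impact_table()


def classify_impact(
    consequence_terms: Sequence[str], table: Mapping[str, str] | None = None
) -> str:
    """Maximum-severity impact class over the given SO terms (unknown → MODIFIER)."""
    if not consequence_terms:
        raise ValidationError("classify_impact requires at least one consequence term")
    table = _DEFAULT_IMPACT_TABLE if table is None else table
    return max(
        (table.get(term, "MODIFIER") for term in consequence_terms),
        key=_SEVERITY.__getitem__,
    )


def classify_pathogenicity(clin_sig: str | None) -> str:
    """Bucket a ClinVar-style clinical-significance label.

    Matching is case-insensitive with spaces and underscores interchangeable;
    anything unrecognized (including an absent label) is UNCLASSIFIED.
    """
    label = (clin_sig or "").strip().lower().replace(" ", "_")
    if label in _P_LP_LABELS:
        return "P_LP"
    if label == "uncertain_significance":
        return "VUS"
    if label == "conflicting_interpretations_of_pathogenicity":
        return "CONFLICTING"
    if label in _BENIGN_LABELS:
        return "BENIGN_LB"
    return "UNCLASSIFIED"


def classify_region(consequence_terms: Sequence[str]) -> str:
    """EXONIC if any exon-resident term; INTRONIC if only intron/splice terms; else OTHER."""
    if not consequence_terms:
        raise ValidationError("classify_region requires at least one consequence term")
    terms = set(consequence_terms)
    if terms & EXONIC_TERMS:
        return "EXONIC"
    if terms <= INTRONIC_TERMS:
        return "INTRONIC"
    return "OTHER"


@dataclass
class AnnotationRecord:
    """Per-variant annotation with derived impact, pathogenicity and region classes."""

    key: VariantKey
    gene: str | None
    consequence_terms: list[str]
    clin_sig: str = ""
    cadd: float | None = None
    impact: str = field(init=False)
    path_class: str = field(init=False)
    region: str = field(init=False)

    def __post_init__(self) -> None:
        if self.cadd is not None and self.cadd < 0:
            raise ValidationError(f"{self.key}: CADD must be non-negative, got {self.cadd}")
        self.impact = classify_impact(self.consequence_terms)
        self.path_class = classify_pathogenicity(self.clin_sig)
        self.region = classify_region(self.consequence_terms)


def assign_genes(
    variants: Iterable[VariantKey], intervals: Iterable[GeneInterval]
) -> dict[VariantKey, set[str]]:
    """Map each variant to every gene whose padded interval contains its position.

    Intervals are 1-based fully closed; membership uses the variant's POS only.
    Variants outside all intervals map to the empty set (dropped downstream).
    """
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        # IntervalTree is half-open, so extend the closed end by one.
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.padded_start, iv.padded_end + 1, iv.gene)
    return {
        key: {hit.data for hit in trees[key.chrom][key.pos]} if key.chrom in trees else set()
        for key in variants
    }


def filter_cadd(records: Iterable[AnnotationRecord], threshold: float = 20.0):
    """Keep records with a CADD score at or above ``threshold``.

    Records lacking a score are excluded (conservative) and counted in a log line.
    """
    if threshold < 0:
        raise ValidationError(f"CADD threshold must be non-negative, got {threshold}")
    records = list(records)
    n_unscored = sum(1 for r in records if r.cadd is None)
    if n_unscored:
        logger.info("filter_cadd: excluded %d record(s) lacking a CADD score", n_unscored)
    return [r for r in records if r.cadd is not None and r.cadd >= threshold]
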