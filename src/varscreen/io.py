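"""Readers and writers for every external format the pipeline touches.

Formats handled:

* multi-sample VCF v4.2 (read via :mod:`cyvcf2`, written as plain text),
  with optional decomposition of multiallelic records into monoallelic rows;
* gene intervals as a 4-column TSV (``gene, chrom, start, end``, 1-based
  closed) or BED (0-based half-open, auto-detected and converted);
* per-variant annotation tables (consequence terms, ClinVar label, CADD);
* reference-panel frequency tables (source, ancestry panel, AF, AN);
* deterministic TSV reports.

Coordinates are VCF-native 1-based throughout; chromosome labels are
normalized to the ``chr`` prefix on read so that the canonical
``chrom_pos_ref_alt`` variant key is stable across inputs.
"""
from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^[ACGT]+$")


def _normalize_chrom(chrom: str) -> str:
    chrom = chrom.strip()
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def _shared_context(ref: str, alt: str) -> int:
    """Length of leading plus trailing sequence context shared by ref and alt."""
    lim = min(len(ref), len(alt))
    p = 0
    while p < lim and ref[p] == alt[p]:
        p += 1
    s = 0
    while s < lim - p and ref[-1 - s] == alt[-1 - s]:
        s += 1
    return p + s


@dataclass(frozen=True, order=True)
class VariantKey:
    """Canonical monoallelic variant identity: (chrom, 1-based pos, ref, alt).

    The string form is ``{chrom}_{pos}_{ref}_{alt}`` (e.g.
    ``chr9_95126582_C_G``) and round-trips through :meth:`parse`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise ValidationError(
                    f"{name} allele {allele!r} is not a non-empty uppercase ACGT string"
                )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical ({self.ref})")
        if _shared_context(self.ref, self.alt) > 1:
            raise ValidationError(
                f"{self.ref}>{self.alt} shares more than one base of leading+trailing "
                "context; input must be left-normalized"
            )

    def __str__(self) -> str:
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        """Parse a ``chrom_pos_ref_alt`` string (chrom may itself contain '_')."""
        parts = text.strip().rsplit("_", 3)
        if len(parts) != 4:
            raise ParseError(f"cannot parse variant key {text!r}")
        chrom, pos, ref, alt = parts
        try:
            pos_i = int(pos)
        except ValueError as exc:
            raise ParseError(f"non-integer position in variant key {text!r}") from exc
        return cls(chrom, pos_i, ref, alt)

    def sort_tuple(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus with raw and padded 1-based closed bounds."""

    gene: str
    chrom: str
    start: int
    end: int
    padded_start: int
    padded_end: int

    @classmethod
    def from_raw(cls, gene: str, chrom: str, start: int, end: int, padding: int) -> "GeneInterval":
        if padding < 0:
            raise ValidationError(f"padding must be non-negative, got {padding}")
        if start > end:
            raise ValidationError(f"{gene}: start {start} > end {end}")
        if start < 1:
            raise ValidationError(f"{gene}: start {start} < 1")
        return cls(
            gene=gene,
            chrom=_normalize_chrom(chrom),
            start=start,
            end=end,
            padded_start=max(1, start - padding),
            padded_end=end + padding,
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.padded_start <= pos <= self.padded_end


@dataclass
class CohortGenotypeTable:
    """Per-variant, per-sample alternate-allele dosages for a diploid cohort.

    ``dosages[v, s]`` counts copies of the focal alternate allele among the
    called alleles of sample ``s`` at variant ``v``; ``called[v, s]`` is the
    number of called alleles (0, 1 or 2). Missing alleles reduce AN rather
    than being imputed: AC = sum of dosages, AN = sum of called alleles.
    """

    variants: list[VariantKey]
    dosages: np.ndarray
    called: np.ndarray
    sample_ids: list[str]
    _index: dict[VariantKey, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        self.called = np.asarray(self.called, dtype=np.int16)
        shape = (len(self.variants), len(self.sample_ids))
        if self.dosages.shape != shape or self.called.shape != shape:
            raise ValidationError(
                f"genotype arrays must have shape {shape}, got "
                f"{self.dosages.shape} / {self.called.shape}"
            )
        if np.any(self.called < 0) or np.any(self.called > 2):
            raise ValidationError("called allele counts must lie in {0, 1, 2}")
        if np.any(self.dosages < 0) or np.any(self.dosages > self.called):
            raise ValidationError("dosage must lie in [0, called alleles]")
        self._index = {}
        for i, key in enumerate(self.variants):
            if key in self._index:
                raise ValidationError(f"duplicate variant key {key}")
            self._index[key] = i

    @classmethod
    def from_dosages(
        cls,
        variants: Sequence[VariantKey],
        dosages: np.ndarray,
        sample_ids: Sequence[str] | None = None,
    ) -> "CohortGenotypeTable":
        """Build a table from a dosage matrix with -1 marking missing genotypes."""
        dosages = np.asarray(dosages, dtype=np.int16)
        if sample_ids is None:
            sample_ids = [f"S{i:04d}" for i in range(dosages.shape[1])]
        called = np.where(dosages >= 0, 2, 0).astype(np.int16)
        return cls(list(variants), np.maximum(dosages, 0), called, list(sample_ids))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def ac(self) -> np.ndarray:
        """Alternate-allele count per variant, recomputed from genotypes."""
        return self.dosages.sum(axis=1)

    @property
    def an(self) -> np.ndarray:
        """Called-allele number per variant."""
        return self.called.sum(axis=1)

    def index_of(self, key: VariantKey) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"variant {key} not present in cohort table") from None


def _prescan_vcf(path: str | Path) -> None:
    """Structural validation so malformed lines are reported with line numbers."""
    opener = gzip.open if str(path).endswith(".gz") else open
    n_cols: int | None = None
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                n_cols = len(line.rstrip("\n").split("\t"))
                if n_cols < 10:
                    raise ParseError(f"{path}: line {lineno}: VCF has no sample columns")
                continue
            if not line.strip():
                continue
            if n_cols is None:
                raise ParseError(f"{path}: line {lineno}: data before #CHROM header")
            cols = line.rstrip("\n").split("\t")
            if len(cols) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, found {len(cols)}"
                )
            try:
                int(cols[1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer POS {cols[1]!r}") from None
            if "GT" not in cols[8].split(":"):
                raise ParseError(f"{path}: line {lineno}: record lacks GT in FORMAT")


def read_cohort_vcf(path: str | Path, decompose: bool = True) -> CohortGenotypeTable:
    """Read a multi-sample VCF into a :class:`CohortGenotypeTable`.

    Multiallelic records are split into one monoallelic row per alternate
    allele when ``decompose`` is set (per-sample dosage counts only the focal
    alt; all called alleles count toward AN). AC/AN are always recomputed
    from the genotypes, never trusted from INFO. Non-ACGT alternate alleles
    (symbolic alleles, spanning deletions ``*``) are dropped with a warning,
    though their called alleles still contribute to AN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_vcf(path)

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantKey] = []
    dos_rows: list[np.ndarray] = []
    call_rows: list[np.ndarray] = []
    n_dropped_alts = 0

    for record in vcf:
        alts = record.ALT
        if len(alts) > 1 and not decompose:
            raise ValidationError(
                f"{path}: multiallelic record at {record.CHROM}:{record.POS} "
                "requires decompose=True"
            )
        genotypes = record.genotypes  # per sample: [allele, allele, ..., phased]
        alleles = [g[:-1] for g in genotypes]
        called = np.array([sum(a >= 0 for a in al) for al in alleles], dtype=np.int16)
        for j, alt in enumerate(alts, start=1):
            if not _ALLELE_RE.match(alt or ""):
                n_dropped_alts += 1
                continue
            key = VariantKey(record.CHROM, record.POS, record.REF, alt)
            dosage = np.array([sum(a == j for a in al) for al in alleles], dtype=np.int16)
            variants.append(key)
            dos_rows.append(dosage)
            call_rows.append(called)

    if n_dropped_alts:
        logger.warning("%s: dropped %d non-ACGT alternate alleles", path, n_dropped_alts)

    n = len(sample_ids)
    dosages = np.vstack(dos_rows) if dos_rows else np.zeros((0, n), dtype=np.int16)
    calls = np.vstack(call_rows) if call_rows else np.zeros((0, n), dtype=np.int16)
    return CohortGenotypeTable(variants, dosages, calls, sample_ids)


_GT_DIPLOID = {0: "0/0", 1: "0/1", 2: "1/1"}
_GT_HAPLOID = {0: "0/.", 1: "1/."}


def write_cohort_vcf(table: CohortGenotypeTable, path: str | Path) -> None:
    """Write the table as a plain-text monoallelic VCF v4.2, sorted by key."""
    order = sorted(range(len(table.variants)), key=lambda i: table.variants[i].sort_tuple())
    contigs = []
    for i in order:
        chrom = table.variants[i].chrom
        if chrom not in contigs:
            contigs.append(chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varscreen\n")
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        for i in order:
            key = table.variants[i]
            gts = []
            for dose, ncall in zip(table.dosages[i], table.called[i]):
                if ncall == 2:
                    gts.append(_GT_DIPLOID[int(dose)])
                elif ncall == 1:
                    gts.append(_GT_HAPLOID[int(dose)])
                else:
                    gts.append("./.")
            fh.write(
                f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_gene_intervals(path: str | Path, padding: int = 10_000) -> list[GeneInterval]:
    """Read gene intervals from TSV (1-based closed) or BED (auto-detected).

    The TSV schema is ``gene, chrom, start, end`` with a header line. A file
    whose first line is not that header is treated as BED (``chrom, start,
    end, name``; 0-based half-open) and converted to 1-based closed.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    header_fields = [f.strip().lower() for f in first.rstrip("\n").split("\t")]

    rows: list[tuple[str, str, int, int]] = []
    if header_fields[:4] == ["gene", "chrom", "start", "end"]:
        df = pd.read_csv(path, sep="\t", dtype=str)
        for lineno, row in enumerate(df.itertuples(index=False), 2):
            try:
                start, end = int(row.start), int(row.end)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate "
                    f"({row.start!r}, {row.end!r})"
                ) from None
            rows.append((row.gene, row.chrom, start, end))
    else:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 3:
            raise SchemaError(f"{path}: BED requires at least 3 columns")
        for lineno, row in enumerate(df.itertuples(index=False), 1):
            try:
                bed_start, bed_end = int(row[1]), int(row[2])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate ({row[1]!r}, {row[2]!r})"
                ) from None
            name = row[3] if df.shape[1] > 3 and isinstance(row[3], str) else f"region{lineno}"
            rows.append((name, row[0], bed_start + 1, bed_end))

    return [GeneInterval.from_raw(gene, chrom, start, end, padding) for gene, chrom, start, end in rows]


def _read_tsv_with_schema(path: str | Path, mandatory: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    extra = [c for c in df.columns if c not in mandatory]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    return df


def read_annotation_table(path: str | Path):
    """Read per-variant annotations: ``variant_key, gene, consequence_terms, clin_sig, cadd``.

    Returns a list of :class:`varscreen.classify.AnnotationRecord` with impact,
    pathogenicity class and region derived from the raw columns.
    """
    from .classify import AnnotationRecord  # local import avoids a cycle

    df = _read_tsv_with_schema(path, ["variant_key", "gene", "consequence_terms", "clin_sig", "cadd"])
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        key = VariantKey.parse(row.variant_key)
        terms = [t.strip() for t in str(row.consequence_terms).split(",") if t.strip()]
        gene = row.gene if isinstance(row.gene, str) and row.gene else None
        clin_sig = row.clin_sig if isinstance(row.clin_sig, str) else ""
        cadd = None
        if isinstance(row.cadd, str) and row.cadd.strip():
            try:
                cadd = float(row.cadd)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric CADD {row.cadd!r}") from None
            if cadd < 0:
                raise ValidationError(f"{path}: line {lineno}: negative CADD {cadd}")
        records.append(
            AnnotationRecord(key=key, gene=gene, consequence_terms=terms, clin_sig=clin_sig, cadd=cadd)
        )
    return records


def read_panel_table(path: str | Path):
    """Read reference-panel frequencies: ``panel, variant_key, af, an`` (+ optional ``source``)."""
    from .sharing import PanelFrequency  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", dtype=str)
    mandatory = ["panel", "variant_key", "af", "an"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    has_source = "source" in df.columns
    extra = [c for c in df.columns if c not in mandatory + ["source"]]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)

    records = []
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        try:
            af = float(row.af)
            an = int(row.an)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: line {lineno}: non-numeric af/an") from None
        if not (0.0 <= af <= 1.0):
            raise ValidationError(f"{path}: line {lineno}: AF {af} outside [0, 1]")
        if an <= 0:
            raise ValidationError(f"{path}: line {lineno}: AN must be positive, got {an}")
        source = row.source if has_source and isinstance(row.source, str) else "default"
        records.append(
            PanelFrequency(
                source=source,
                panel=row.panel,
                key=VariantKey.parse(row.variant_key),
                af=af,
                an=an,
            )
        )
    return records


def write_report(records: Iterable[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write a TSV report with deterministic column and row order.

    Rows carrying a ``variant_key`` column are sorted by (chrom, pos, ref,
    alt); column order is the order of first appearance.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if "variant_key" in df.columns and len(df):
        sort_keys = df["variant_key"].map(lambda s: VariantKey.parse(s).sort_tuple())
        df = df.iloc[sort_keys.argsort(kind="stable").to_numpy()]
    df.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a TSV report written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t")
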