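"""Cross-ancestry variant sharing.

For a chosen cohort variant set and a table of reference-panel frequencies,
count how many set variants are shared with each ancestry panel of a given
reference database (source), and how many are cohort-unique, i.e.
monomorphic in every panel of that source. A variant is "shared" with a
panel iff a record for that (source, panel, variant) exists with AF > 0;
an absent record counts as AF = 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .io import VariantKey


@dataclass(frozen=True)
class PanelFrequency:
    """One reference-panel frequency record: (source database, ancestry panel, variant)."""

    source: str
    panel: str
    key: VariantKey
    af: float
    an: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.af <= 1.0):
            raise ValidationError(f"{self.key}: panel AF {self.af} outside [0, 1]")
        if self.an <= 0:
            raise ValidationError(f"{self.key}: panel AN must be positive, got {self.an}")


@dataclass(frozen=True)
class SharingReport:
    """Per-source sharing summary for a variant set."""

    source: str
    n_total: int
    per_panel: dict[str, tuple[int, int]]  # panel -> (n_shared, n_total)
    n_unique: int  # variants with AF = 0 (or absent) in every panel of the source


def shared_counts(
    variant_set: Iterable[VariantKey],
    panels: Iterable[PanelFrequency],
    source: str,
) -> SharingReport:
    """Sharing report of ``variant_set`` against every ancestry panel of ``source``."""
    keys = set(variant_set)
    if not keys:
        raise ValidationError("shared_counts requires a non-empty variant set")
    panels = list(panels)
    sources = {p.source for p in panels}
    if panels and source not in sources:
        raise ValidationError(
            f"unknown source {source!r}; available sources: {sorted(sources)}"
        )

    present: dict[str, set[VariantKey]] = {}
    for p in panels:
        if p.source != source:
            continue
        present.setdefault(p.panel, set())
        if p.af > 0.0 and p.key in keys:
            present[p.panel].add(p.key)

    n_total = len(keys)
    per_panel = {panel: (len(hits), n_total) for panel, hits in sorted(present.items())}
    union: set[VariantKey] = set()
    for hits in present.values():
        union |= hits
    return SharingReport(
        source=source,
        n_total=n_total,
        per_panel=per_panel,
        n_unique=n_total - len(union),
    )


def sharing_by_source(
    variant_set: Iterable[VariantKey],
    panels: Iterable[PanelFrequency],
    sources: Sequence[str],
) -> list[SharingReport]:
    """One independent :func:`shared_counts` report per source."""
    if not sources:
        raise ValidationError("sharing_by_source requires at least one source")
    keys = set(variant_set)
    panels = list(panels)
    return [shared_counts(keys, panels, source) for source in sources]
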