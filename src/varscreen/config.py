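"""Analysis configuration.

FilterConfig gathers the thresholds that drive the screening cascade:
the rare/common MAF boundary, the CADD deleteriousness cut-off, the
gene-interval padding and the family-wise significance level used after
Bonferroni correction.
"""
from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the variant screening cascade.

    Parameters
    ----------
    maf_rare_threshold
        Variants with minor allele frequency below this are "rare" (default 0.01).
    cadd_threshold
        PHRED-scaled CADD score at or above which a variant is kept by the
        deleteriousness filter (default 20, the top 1% of substitutions).
    padding_bp
        Symmetric padding added to gene intervals, in base pairs (default 10000).
    alpha
        Family-wise error rate for Bonferroni-corrected significance (default 0.05).
    """

    maf_rare_threshold: float = 0.01
    cadd_threshold: float = 20.0
    padding_bp: int = 10_000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.maf_rare_threshold > 0):
            raise ValidationError("maf_rare_threshold must be strictly positive")
        if not (self.cadd_threshold > 0):
            raise ValidationError("cadd_threshold must be strictly positive")
        if self.padding_bp < 0:
            raise ValidationError("padding_bp must be non-negative")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        """Load a config from a YAML mapping; absent keys keep their defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def merged(self, **overrides) -> "FilterConfig":
        """Return a copy with non-None overrides applied (CLI > file > default)."""
        updates = {k: v for k, v in overrides.items() if v is not None}
        return replace(self, **updates) if updates else self
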