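"""Genomic comparator covariates: TMB class, APOBEC enrichment class,
clonal mutation fraction.

The APOBEC fold-enrichment E is consumed as an input, not computed here;
its trinucleotide-context estimation belongs to upstream WGS pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

TMB_HIGH = "high"
TMB_LOW = "low"
APOBEC_NO = "no"
APOBEC_LOW = "low"
APOBEC_MEDIUM = "medium"
APOBEC_HIGH = "high"

#: TMB high/low boundary in mutations per megabase (>= threshold is high).
DEFAULT_TMB_THRESHOLD = 10.0
#: Variant copy number above which (strictly) a mutation is called clonal.
DEFAULT_CLONAL_VCN_THRESHOLD = 0.75


@dataclass
class GenomicRecord:
    """Per-sample genomic covariates."""

    tmb: float
    apobec_E: float
    apobec_detected: bool
    variant_copy_numbers: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tmb < 0:
            raise ValueError("tmb must be >= 0")
        if self.apobec_E < 0:
            raise ValueError("apobec_E must be >= 0")


def classify_tmb(tmb: float, threshold: float = DEFAULT_TMB_THRESHOLD) -> str:
    """high when tmb >= threshold (default 10 mutations/Mb), else low."""
    if tmb < 0:
        raise ValueError("tmb must be >= 0")
    return TMB_HIGH if tmb >= threshold else TMB_LOW


def classify_apobec(E: float, detected: bool) -> str:
    """APOBEC mutagenesis class from fold-enrichment E.

    no enrichment detected -> "no"; otherwise high when E >= 3, medium when
    2 <= E < 3, low when E < 2.
    """
    if E < 0:
        raise ValueError("apobec enrichment E must be >= 0")
    if not detected:
        return APOBEC_NO
    if E >= 3:
        return APOBEC_HIGH
    if E >= 2:
        return APOBEC_MEDIUM
    return APOBEC_LOW


def apobec_high_vs_nonhigh(E: float, detected: bool) -> bool:
    """The binary grouping used in outcome comparisons: True iff class is high."""
    return classify_apobec(E, detected) == APOBEC_HIGH


def clonal_fraction(
    variant_copy_numbers: Sequence[float],
    threshold: float = DEFAULT_CLONAL_VCN_THRESHOLD,
) -> float:
    """Fraction of mutations with variant copy number strictly > threshold."""
    vcn = np.asarray(variant_copy_numbers, dtype=float)
    if vcn.size == 0:
        raise ValueError("variant copy number list is empty")
    return float(np.mean(vcn > threshold))
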