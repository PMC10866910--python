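"""Protein-level analog of the TSE score from immunofluorescence-derived
quantities.

The score combines CD4/CD8 cell densities (cells per mm^2) with FAP/PDPN
area fractions (percent of tissue area) as
``log10(1+cd4) + log10(1+cd8) - log10(1+fap) - log10(1+pdpn)``.
Caveat: densities and percentages enter the same log transform with their
native (mixed) units; any positive rescaling preserves ranks and AUC.
The positive/negative cutoff defaults to 0 — no numeric cutoff is
published for the protein score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PROTEIN_POSITIVE = "positive"
PROTEIN_NEGATIVE = "negative"
MARKER_COLUMNS = ("cd4_density", "cd8_density", "fap_area_pct", "pdpn_area_pct")


@dataclass
class MarkerQuantification:
    """Quantified immunofluorescence markers for one sample.

    ``None`` marks a failed quantification; the protein score is undefined
    for samples with any missing marker.
    """

    cd4_density: float | None
    cd8_density: float | None
    fap_area_pct: float | None
    pdpn_area_pct: float | None
    tissue_area: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cd4_density", "cd8_density"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fap_area_pct", "pdpn_area_pct"):
            value = getattr(self, name)
            if value is not None and not 0 <= value <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")
        if self.tissue_area <= 0:
            raise ValueError("tissue_area must be > 0")

    @property
    def complete(self) -> bool:
        return all(
            getattr(self, name) is not None
            for name in ("cd4_density", "cd8_density", "fap_area_pct", "pdpn_area_pct")
        )


def cell_density(cell_count: int, tissue_area: float) -> float:
    """Cells per mm^2: count divided by tissue area."""
    if tissue_area <= 0:
        raise ValueError("tissue_area must be > 0")
    if cell_count < 0:
        raise ValueError("cell_count must be >= 0")
    return cell_count / tissue_area


def area_fraction(marker_area: float, tissue_area: float) -> float:
    """Marker-positive area as a percentage of total tissue area."""
    if tissue_area <= 0:
        raise ValueError("tissue_area must be > 0")
    if marker_area < 0:
        raise ValueError("marker_area must be >= 0")
    if marker_area > tissue_area:
        raise ValueError("marker_area cannot exceed tissue_area")
    return 100.0 * marker_area / tissue_area


def tse_protein(q: MarkerQuantification) -> float:
    """TSE-protein score; raises if any of the four markers is missing."""
    if not q.complete:
        raise ValueError("protein score undefined: missing marker quantification")
    t_part = math.log10(1 + q.cd4_density) + math.log10(1 + q.cd8_density)
    s_part = math.log10(1 + q.fap_area_pct) + math.log10(1 + q.pdpn_area_pct)
    return t_part - s_part


def categorize_protein(score: float, cutoff: float = 0.0) -> str:
    """positive when score >= cutoff, else negative."""
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    return PROTEIN_POSITIVE if score >= cutoff else PROTEIN_NEGATIVE


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read the marker CSV (sample, cd4_density, cd8_density, fap_area_pct,
    pdpn_area_pct, tissue_area_mm2); empty cells mean failed quantification."""
    frame = pd.read_csv(path)
    missing = {"sample", *MARKER_COLUMNS} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame.set_index("sample")


def score_marker_table(frame: pd.DataFrame, cutoff: float = 0.0) -> pd.DataFrame:
    """TSE-protein score and category per sample; NaN where markers are missing."""
    scores = []
    for sample, row in frame.iterrows():
        values = [row.get(c) for c in MARKER_COLUMNS]
        if any(pd.isna(v) for v in values):
            scores.append((sample, float("nan"), ""))
            continue
        q = MarkerQuantification(*values, tissue_area=float(row.get("tissue_area_mm2", 1.0)))
        score = tse_protein(q)
        scores.append((sample, score, categorize_protein(score, cutoff)))
    return pd.DataFrame(scores, columns=["sample", "tse_protein", "category"]).set_index("sample")
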