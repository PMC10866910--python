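"""Expression-matrix and gene-set (GMT) input, validation and coverage reporting.

Gene identifier matching is exact-string and case-sensitive throughout:
alias/symbol harmonization is version-dependent and must happen upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognized signature group tags (GMT description field).
GROUP_T = "T-cell"
GROUP_OTHER = "other-immune"
GROUP_STROMAL = "stromal"
VALID_GROUPS = frozenset({GROUP_T, GROUP_OTHER, GROUP_STROMAL})

#: Published fixed membership of the global T-cell meta-signature.
DEFAULT_GLOBAL_T_MEMBERS = (
    "Cytotoxic CD8 T cell",
    "T cell inflamed GEP",
    "tGE8",
    "T cell signature",
    "IFN gamma",
    "Immune gene signature and chemoattractants",
)

#: Published fixed membership of the global stromal meta-signature.
DEFAULT_GLOBAL_S_MEMBERS = (
    "Stromal signature",
    "Fibroblasts",
    "EMT/stroma core genes",
    "CAF",
    "TBRS",
)


class ExpressionMatrixError(ValueError):
    """Malformed expression matrix input."""


class GMTError(ValueError):
    """Malformed GMT gene-set input."""


@dataclass
class ExpressionMatrix:
    """Normalized log-scale expression, genes x samples.

    Values are expected to already be normalized (e.g. variance-stabilized
    counts); this package never renormalizes raw counts.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ExpressionMatrixError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids) or n_samples != len(self.sample_ids):
            raise ExpressionMatrixError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids / {len(self.sample_ids)} sample ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExpressionMatrixError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExpressionMatrixError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ExpressionMatrixError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class SignatureSet:
    """Named gene sets with group tags and global-membership lists."""

    signatures: dict[str, list[str]]
    group: dict[str, str] = field(default_factory=dict)
    global_T_members: list[str] = field(default_factory=list)
    global_S_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, genes in self.signatures.items():
            if not genes:
                raise GMTError(f"signature {name!r} has an empty gene list")
        for name in self.signatures:
            self.group.setdefault(name, GROUP_OTHER)
        for name, tag in self.group.items():
            if tag not in VALID_GROUPS:
                raise GMTError(f"signature {name!r} has unknown group tag {tag!r}")
        for member in list(self.global_T_members) + list(self.global_S_members):
            if member not in self.signatures:
                raise GMTError(f"global member {member!r} not among signatures")

    @property
    def names(self) -> list[str]:
        return list(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample expression TSV (first column gene id, header = sample ids)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ExpressionMatrixError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise ExpressionMatrixError(f"{path}: no sample columns")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ExpressionMatrixError(f"{path}: duplicate gene ids {dupes[:5]}")
    if frame.columns.has_duplicates:
        raise ExpressionMatrixError(f"{path}: duplicate sample ids")
    non_numeric = [c for c, d in frame.dtypes.items() if not np.issubdtype(d, np.number)]
    if non_numeric:
        raise ExpressionMatrixError(f"{path}: non-numeric cells in columns {non_numeric[:5]}")
    return ExpressionMatrix.from_frame(frame)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> Path:
    """Write the TSV dialect read back by :func:`read_expression_matrix`."""
    path = Path(path)
    frame = expr.to_frame()
    frame.index.name = "gene_id"
    # %.17g guarantees exact binary round-trip of doubles through text
    frame.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_gmt(path: str | Path) -> SignatureSet:
    """Parse a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``.

    The description field doubles as the group tag when it is one of
    ``T-cell`` / ``other-immune`` / ``stromal``; any other description maps
    to ``other-immune``.  Global memberships default to the published fixed
    lists restricted to the names present in the file.
    """
    path = Path(path)
    signatures: dict[str, list[str]] = {}
    group: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if name in signatures:
                raise GMTError(f"{path}:{lineno}: duplicate signature name {name!r}")
            if not genes:
                raise GMTError(f"{path}:{lineno}: signature {name!r} has no genes")
            signatures[name] = genes
            group[name] = description if description in VALID_GROUPS else GROUP_OTHER
    if not signatures:
        raise GMTError(f"{path}: no signatures found")
    global_t = [n for n in DEFAULT_GLOBAL_T_MEMBERS if n in signatures]
    global_s = [n for n in DEFAULT_GLOBAL_S_MEMBERS if n in signatures]
    if not global_t:
        global_t = [n for n, g in group.items() if g == GROUP_T]
    if not global_s:
        global_s = [n for n, g in group.items() if g == GROUP_STROMAL]
    return SignatureSet(signatures, group, global_t, global_s)


def write_gmt(sigs: SignatureSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        for name, genes in sigs.signatures.items():
            handle.write("\t".join([name, sigs.group[name], *genes]) + "\n")
    return path


def validate_signatures(
    sigs: SignatureSet,
    expr: ExpressionMatrix,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Report per-signature gene coverage against an expression matrix.

    Returns a frame indexed by signature name with columns ``n_genes``,
    ``n_found``, ``coverage`` and ``flagged`` (coverage < ``min_coverage``).
    Reporting only; nothing is mutated.
    """
    present = set(expr.gene_ids)
    rows = []
    for name, genes in sigs.signatures.items():
        n_found = sum(1 for g in genes if g in present)
        coverage = n_found / len(genes)
        rows.append((name, len(genes), n_found, coverage, coverage < min_coverage))
    report = pd.DataFrame(
        rows, columns=["signature", "n_genes", "n_found", "coverage", "flagged"]
    ).set_index("signature")
    flagged = report.index[report["flagged"]].tolist()
    if flagged:
        logger.warning("signatures below coverage %.2f: %s", min_coverage, flagged)
    return report
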