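"""Core scoring: median centering, signature scores, AUC/SD screening,
global T-cell and stromal meta-signatures, and the TSE score with its
positive/neutral/negative categories.

The computation is cohort-relative: genes are median-centered across the
samples at hand, so adding or removing samples changes every score.  Score
a cohort as a whole, not sample by sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tsescore.signature_io import ExpressionMatrix, SignatureSet, validate_signatures
from tsescore.stats_inference import roc_auc

logger = logging.getLogger(__name__)

CATEGORY_POSITIVE = "positive"
CATEGORY_NEUTRAL = "neutral"
CATEGORY_NEGATIVE = "negative"

#: Default TSE category cutoff: score >= +0.5 positive, <= -0.5 negative.
DEFAULT_CUTOFF = 0.5


@dataclass
class SignatureScores:
    """Per-signature, per-sample scores (mean centered expression over genes)."""

    scores: pd.DataFrame  # signatures x samples

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("signature scores must be finite")

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class TSEResult:
    """Per-sample global T score, global stromal score, TSE score and category."""

    global_T: pd.Series
    global_S: pd.Series
    tse: pd.Series
    category: pd.Series
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if not self.global_T.index.equals(self.global_S.index):
            raise ValueError("global_T and global_S sample ids differ")
        if not np.allclose(self.tse, self.global_T - self.global_S):
            raise ValueError("tse must equal global_T - global_S")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "global_T": self.global_T,
                "global_S": self.global_S,
                "tse": self.tse,
                "category": self.category,
            }
        ).rename_axis("sample")


def median_center(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center every gene at its median across samples (per-gene, cohort-wide)."""
    if expr.n_samples == 0 or expr.n_genes == 0:
        raise ValueError("empty expression matrix")
    medians = np.median(expr.values, axis=1, keepdims=True)
    return ExpressionMatrix(expr.values - medians, expr.gene_ids, expr.sample_ids)


def signature_score(centered: ExpressionMatrix, genes) -> pd.Series:
    """Per-sample unweighted mean of centered expression over the signature's
    genes that are present in the matrix."""
    index = centered.gene_index()
    rows = [index[g] for g in genes if g in index]
    if not rows:
        raise ValueError("no signature gene present in the expression matrix")
    values = centered.values[rows].mean(axis=0)
    return pd.Series(values, index=centered.sample_ids)


def score_all(
    centered: ExpressionMatrix,
    sigs: SignatureSet,
    min_coverage: float = 0.5,
) -> SignatureScores:
    """Score every signature; signatures below ``min_coverage`` gene coverage
    are excluded (with a warning) and absent from the output."""
    report = validate_signatures(sigs, centered, min_coverage=min_coverage)
    kept = [name for name in sigs.names if not report.loc[name, "flagged"]]
    if not kept:
        raise ValueError("no signature passed the coverage filter")
    frame = pd.DataFrame(
        {name: signature_score(centered, sigs.signatures[name]) for name in kept}
    ).T
    frame.columns = centered.sample_ids
    return SignatureScores(frame)


def screen_signatures(
    scores: SignatureScores,
    response,
    auc_threshold: float = 0.7,
) -> pd.DataFrame:
    """Screen signatures on discriminatory power: oriented AUC for the binary
    response plus the standard deviation of scores across samples.

    AUC is reported as max(AUC, 1-AUC) with the orientation recorded, so the
    screening measures discrimination irrespective of direction.  ``selected``
    is AUC > ``auc_threshold``.
    """
    label = np.asarray(response).astype(int)
    if label.min() == label.max():
        raise ValueError("both response classes must be present")
    rows = []
    for name in scores.signature_names:
        values = scores.scores.loc[name].to_numpy(dtype=float)
        raw = roc_auc(values, label).auc
        oriented = max(raw, 1.0 - raw)
        rows.append(
            {
                "signature": name,
                "auc": oriented,
                "direction": 1 if raw >= 0.5 else -1,
                "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                "selected": oriented > auc_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("signature")


def global_scores(scores: SignatureScores, members_T, members_S) -> tuple[pd.Series, pd.Series]:
    """Global meta-signatures: per-sample unweighted mean of member signature scores."""
    members_T, members_S = list(members_T), list(members_S)
    if not members_T or not members_S:
        raise ValueError("member lists must be non-empty")
    for member in members_T + members_S:
        if member not in scores.scores.index:
            raise KeyError(f"global member {member!r} missing from signature scores")
    global_t = scores.scores.loc[members_T].mean(axis=0)
    global_s = scores.scores.loc[members_S].mean(axis=0)
    return global_t, global_s


def tse_score(global_T: pd.Series, global_S: pd.Series, cutoff: float = DEFAULT_CUTOFF) -> TSEResult:
    """TSE score: arithmetic difference global_T - global_S, plus categories."""
    if not global_T.index.equals(global_S.index):
        raise ValueError("misaligned sample ids between global_T and global_S")
    tse = global_T - global_S
    category = pd.Series([categorize(v, cutoff) for v in tse], index=tse.index)
    return TSEResult(global_T=global_T, global_S=global_S, tse=tse, category=category, cutoff=cutoff)


def categorize(tse: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """positive when tse >= cutoff, negative when tse <= -cutoff, else neutral.

    Both boundaries are closed, matching the published rule (>= 0.5 / <= -0.5).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if tse >= cutoff:
        return CATEGORY_POSITIVE
    if tse <= -cutoff:
        return CATEGORY_NEGATIVE
    return CATEGORY_NEUTRAL


def score_cohort(
    expr: ExpressionMatrix,
    sigs: SignatureSet,
    cutoff: float = DEFAULT_CUTOFF,
    min_coverage: float = 0.5,
    rescreen_response=None,
    auc_threshold: float = 0.7,
) -> TSEResult:
    """End-to-end scoring: median-center, score signatures, average the global
    memberships, subtract, categorize.

    By default the fixed published global memberships (as carried by the
    SignatureSet) are used.  When ``rescreen_response`` labels are given, the
    memberships are re-derived data-driven: signatures with oriented AUC >
    ``auc_threshold`` are kept, split by their group tag.
    """
    centered = median_center(expr)
    scores = score_all(centered, sigs, min_coverage=min_coverage)
    members_t = [m for m in sigs.global_T_members if m in scores.scores.index]
    members_s = [m for m in sigs.global_S_members if m in scores.scores.index]
    if rescreen_response is not None:
        report = screen_signatures(scores, rescreen_response, auc_threshold=auc_threshold)
        selected = set(report.index[report["selected"]])
        members_t = [n for n in scores.signature_names if n in selected and sigs.group[n] == "T-cell"]
        members_s = [n for n in scores.signature_names if n in selected and sigs.group[n] == "stromal"]
        logger.info("re-screened memberships: T=%s S=%s", members_t, members_s)
    global_t, global_s = global_scores(scores, members_t, members_s)
    return tse_score(global_t, global_s, cutoff=cutoff)
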