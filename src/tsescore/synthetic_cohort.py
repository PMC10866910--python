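"""Synthetic cohort generator with planted three-group structure.

Emulates the five input kinds the pipeline consumes — expression matrix,
gene-set collection, clinical table, per-sample TCR clonotype tables and
immunofluorescence marker quantities — with a planted T-cell-high / mixed /
stroma-high group structure linked to response, survival, repertoire
evenness and marker levels.

Distributional choices are conventions, not reproductions: the source
cohort's expression distribution is not described anywhere, so the
generator mimics variance-stabilized output (roughly homoskedastic
log-scale values) with Gaussian gene-wise noise.  Generated gene sets are
disjoint by default to keep recovery tests interpretable; ``overlap_fraction``
introduces overlap when wanted.

All randomness flows from a single seed; per-modality substreams are
derived deterministically, so equal seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tsescore.signature_io import (
    GROUP_OTHER,
    GROUP_STROMAL,
    GROUP_T,
    ExpressionMatrix,
    SignatureSet,
    write_expression_matrix,
    write_gmt,
)
from tsescore.tcr_repertoire import ClonotypeTable

#: Planted group labels, chosen to match the TSE categories they should map to.
GROUP_LABELS = ("positive", "neutral", "negative")


def _check_probs(name: str, probs, n: int) -> tuple[float, ...]:
    probs = tuple(float(p) for p in probs)
    if len(probs) != n:
        raise ValueError(f"{name} must have {n} entries")
    if any(p < 0 or p > 1 for p in probs):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    return probs


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``response_probs`` defaults to the planted generative target of
    (0.67, 0.21, 0.00) response probability for the TSE-positive-like,
    neutral-like and TSE-negative-like groups.
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_signatures_T: int = 6
    n_signatures_S: int = 5
    n_signatures_other: int = 8
    genes_per_signature: int = 10
    group_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    effect_T: float = 1.5
    effect_S: float = 1.5
    response_probs: tuple[float, float, float] = (0.67, 0.21, 0.00)
    baseline_hazard: float = 0.05
    hazard_ratio_by_group: tuple[float, float, float] = (0.5, 1.0, 2.0)
    censoring_rate: float = 0.02
    tcr_clones: int = 200
    tcr_reads: int = 5000
    tcr_evenness_by_group: tuple[float, float, float] = (5.0, 1.0, 0.2)
    noise_sd: float = 1.0
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "genes_per_signature", "tcr_clones", "tcr_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("n_signatures_T", "n_signatures_S", "n_signatures_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_signatures_T == 0 or self.n_signatures_S == 0:
            raise ValueError("need at least one T and one stromal signature")
        self.group_probs = _check_probs("group_probs", self.group_probs, 3)
        if abs(sum(self.group_probs) - 1.0) > 1e-12:
            raise ValueError("group_probs must sum to 1 within 1e-12")
        self.response_probs = _check_probs("response_probs", self.response_probs, 3)
        for name in ("effect_T", "effect_S"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.baseline_hazard <= 0 or self.censoring_rate < 0:
            raise ValueError("hazard parameters must be positive")
        if any(h <= 0 for h in self.hazard_ratio_by_group):
            raise ValueError("hazard ratios must be > 0")
        if any(a <= 0 for a in self.tcr_evenness_by_group):
            raise ValueError("tcr evenness concentrations must be > 0")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        total_sig_genes = (
            self.n_signatures_T + self.n_signatures_S + self.n_signatures_other
        ) * self.genes_per_signature
        if total_sig_genes > self.n_genes:
            raise ValueError("n_genes too small for the requested signatures")


@dataclass
class SyntheticTruth:
    """Planted structure: per-sample group label and per-signature shift."""

    group_label: pd.Series
    signature_shift: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if self.group_label.isna().any():
            raise ValueError("every sample must have a group label")
        if not set(self.group_label) <= set(GROUP_LABELS):
            raise ValueError("unknown group labels")


@dataclass
class SyntheticCohort:
    """Bundle of all generated inputs plus the planted truth."""

    expression: ExpressionMatrix
    signatures: SignatureSet
    clinical: pd.DataFrame
    clonotypes: list[ClonotypeTable]
    markers: pd.DataFrame
    truth: SyntheticTruth


def _make_signatures(config: SimulationConfig, rng: np.random.Generator, gene_ids: list[str]) -> SignatureSet:
    counts = {
        GROUP_T: config.n_signatures_T,
        GROUP_STROMAL: config.n_signatures_S,
        GROUP_OTHER: config.n_signatures_other,
    }
    prefixes = {GROUP_T: "T-sig", GROUP_STROMAL: "S-sig", GROUP_OTHER: "O-sig"}
    signatures: dict[str, list[str]] = {}
    group: dict[str, str] = {}
    cursor = 0
    used: list[str] = []
    for tag in (GROUP_T, GROUP_STROMAL, GROUP_OTHER):
        for i in range(counts[tag]):
            genes = gene_ids[cursor : cursor + config.genes_per_signature]
            cursor += config.genes_per_signature
            n_overlap = int(config.overlap_fraction * len(genes))
            if n_overlap and used:
                shared = rng.choice(used, size=n_overlap, replace=False if n_overlap <= len(used) else True)
                genes = list(shared) + genes[n_overlap:]
            name = f"{prefixes[tag]}-{i + 1:02d}"
            signatures[name] = list(genes)
            group[name] = tag
            used.extend(g for g in genes if g not in used)
    global_t = [n for n, g in group.items() if g == GROUP_T]
    global_s = [n for n, g in group.items() if g == GROUP_STROMAL]
    return SignatureSet(signatures, group, global_t, global_s)


def _make_expression(
    config: SimulationConfig,
    rng: np.random.Generator,
    sigs: SignatureSet,
    gene_ids: list[str],
    sample_ids: list[str],
    groups: np.ndarray,
) -> tuple[ExpressionMatrix, dict[str, float]]:
    baseline = rng.normal(loc=8.0, scale=2.0, size=config.n_genes)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_samples))
    index = {g: i for i, g in enumerate(gene_ids)}
    shifts: dict[str, float] = {}
    for name, genes in sigs.signatures.items():
        tag = sigs.group[name]
        rows = [index[g] for g in genes]
        if tag == GROUP_T:
            values[np.ix_(rows, np.flatnonzero(groups == 0))] += config.effect_T
            shifts[name] = config.effect_T
        elif tag == GROUP_STROMAL:
            values[np.ix_(rows, np.flatnonzero(groups == 2))] += config.effect_S
            shifts[name] = config.effect_S
        else:
            shifts[name] = 0.0
    return ExpressionMatrix(values, gene_ids, sample_ids), shifts


def _make_clinical(
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_ids: list[str],
    groups: np.ndarray,
) -> pd.DataFrame:
    n = config.n_samples
    response_p = np.asarray(config.response_probs)[groups]
    response = rng.binomial(1, response_p)
    hazards = config.baseline_hazard * np.asarray(config.hazard_ratio_by_group)[groups]
    os_latent = rng.exponential(1.0 / hazards)
    pfs_latent = rng.exponential(1.0 / (2.0 * hazards))
    if config.censoring_rate > 0:
        os_censor = rng.exponential(1.0 / config.censoring_rate, size=n)
        pfs_censor = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        os_censor = np.full(n, np.inf)
        pfs_censor = np.full(n, np.inf)
    tmb = rng.lognormal(mean=np.log(8.0), sigma=0.6, size=n)
    apobec_E = rng.lognormal(mean=np.log(2.0), sigma=0.5, size=n)
    return pd.DataFrame(
        {
            "sample": sample_ids,
            "response": response,
            "os_time": np.minimum(os_latent, os_censor),
            "os_event": (os_latent <= os_censor).astype(int),
            "pfs_time": np.minimum(pfs_latent, pfs_censor),
            "pfs_event": (pfs_latent <= pfs_censor).astype(int),
            "tmb": tmb,
            "apobec_E": apobec_E,
            "apobec_detected": rng.binomial(1, 0.7, size=n).astype(bool),
            "cps": rng.integers(0, 101, size=n),
            "pretreated": rng.binomial(1, 0.5, size=n).astype(bool),
            "biopsy_site": rng.choice(["lymph_node", "liver", "primary", "other"], size=n),
            "sex": rng.choice(["F", "M"], size=n),
            "age": rng.normal(65.0, 9.0, size=n).round().astype(int),
        }
    ).set_index("sample")


def _make_clonotypes(
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_ids: list[str],
    groups: np.ndarray,
) -> list[ClonotypeTable]:
    evenness = np.asarray(config.tcr_evenness_by_group)
    tables = []
    for sample, g in zip(sample_ids, groups):
        alpha = np.full(config.tcr_clones, evenness[g])
        weights = rng.dirichlet(alpha)
        counts = rng.multinomial(config.tcr_reads, weights)
        keep = counts >= 1
        tables.append(
            ClonotypeTable(
                sample_id=sample,
                clonotype_ids=[f"clone_{i:04d}" for i in np.flatnonzero(keep)],
                reads=counts[keep],
            )
        )
    return tables


def _make_markers(
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_ids: list[str],
    groups: np.ndarray,
) -> pd.DataFrame:
    # log-mean marker levels concordant with the planted expression shifts
    density_mu = np.log([150.0, 50.0, 15.0])
    area_mu = np.log([2.0, 6.0, 20.0])
    n = len(sample_ids)
    cd4 = np.exp(rng.normal(density_mu[groups], 0.6))
    cd8 = np.exp(rng.normal(density_mu[groups] - 0.2, 0.6))
    fap = np.minimum(100.0, np.exp(rng.normal(area_mu[groups], 0.6)))
    pdpn = np.minimum(100.0, np.exp(rng.normal(area_mu[groups] - 0.3, 0.6)))
    return pd.DataFrame(
        {
            "sample": sample_ids,
            "cd4_density": cd4,
            "cd8_density": cd8,
            "fap_area_pct": fap,
            "pdpn_area_pct": pdpn,
            "tissue_area_mm2": np.exp(rng.normal(np.log(2.0), 0.3, size=n)),
        }
    ).set_index("sample")


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort; equal config (incl. seed) gives
    bit-identical results."""
    streams = [
        np.random.default_rng(child)
        for child in np.random.SeedSequence(config.seed).spawn(6)
    ]
    rng_groups, rng_sigs, rng_expr, rng_clin, rng_tcr, rng_marker = streams

    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    gene_ids = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    groups = rng_groups.choice(3, size=config.n_samples, p=config.group_probs)

    sigs = _make_signatures(config, rng_sigs, gene_ids)
    expression, shifts = _make_expression(config, rng_expr, sigs, gene_ids, sample_ids, groups)
    clinical = _make_clinical(config, rng_clin, sample_ids, groups)
    clonotypes = _make_clonotypes(config, rng_tcr, sample_ids, groups)
    markers = _make_markers(config, rng_marker, sample_ids, groups)
    truth = SyntheticTruth(
        group_label=pd.Series([GROUP_LABELS[g] for g in groups], index=sample_ids, name="group"),
        signature_shift=shifts,
        seed=config.seed,
    )
    return SyntheticCohort(expression, sigs, clinical, clonotypes, markers, truth)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort to plain-text files; returns the path of each artifact.

    Layout: ``expression.tsv``, ``signatures.gmt``, ``clinical.tsv``,
    ``markers.csv``, ``truth.tsv`` and one ``tcr/<sample>.tsv`` per sample.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["expression"] = write_expression_matrix(cohort.expression, directory / "expression.tsv")
    paths["signatures"] = write_gmt(cohort.signatures, directory / "signatures.gmt")
    paths["clinical"] = directory / "clinical.tsv"
    cohort.clinical.to_csv(paths["clinical"], sep="\t", float_format="%.10g")
    paths["markers"] = directory / "markers.csv"
    cohort.markers.to_csv(paths["markers"], float_format="%.10g")
    tcr_dir = directory / "tcr"
    tcr_dir.mkdir(exist_ok=True)
    for table in cohort.clonotypes:
        path = tcr_dir / f"{table.sample_id}.tsv"
        pd.DataFrame({"clonotype_id": table.clonotype_ids, "reads": table.reads}).to_csv(
            path, sep="\t", index=False
        )
        paths[f"tcr/{table.sample_id}"] = path
    paths["truth"] = directory / "truth.tsv"
    cohort.truth.group_label.rename_axis("sample").to_frame().to_csv(paths["truth"], sep="\t")
    return paths
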