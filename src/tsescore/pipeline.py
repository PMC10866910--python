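"""End-to-end orchestration: simulate/load -> score -> classify -> evaluate,
with a machine-readable JSON summary and per-sample TSV outputs.

Samples are aligned across tables by exact id intersection; excluded ids
are logged and listed in the validation report.  All randomness flows from
the single seed recorded in the summary's provenance block.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tsescore import __version__
from tsescore.genomic_features import apobec_high_vs_nonhigh, classify_tmb
from tsescore.protein_score import score_marker_table
from tsescore.signature_io import read_expression_matrix, read_gmt
from tsescore.stats_inference import cox_fit, delong_test, fisher_exact, logrank, roc_auc
from tsescore.synthetic_cohort import SimulationConfig, SyntheticCohort, generate_cohort, write_cohort
from tsescore.tse_scoring import DEFAULT_CUTOFF, score_cohort

logger = logging.getLogger(__name__)

KNOWN_PREDICTORS = ("tse", "global_T", "global_S", "tmb", "apobec")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulated or file-backed inputs)."""

    out_dir: str | Path = "tse_run"
    seed: int = 0
    cutoff: float = DEFAULT_CUTOFF
    rescreen: bool = False
    auc_threshold: float = 0.7
    predictors: tuple[str, ...] = ("tse", "tmb", "apobec")
    simulation: SimulationConfig | None = None
    expression_path: str | Path | None = None
    gmt_path: str | Path | None = None
    clinical_path: str | Path | None = None
    markers_path: str | Path | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.predictors) - set(KNOWN_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors {sorted(unknown)}; known: {KNOWN_PREDICTORS}")
        if self.simulation is None and (self.expression_path is None or self.clinical_path is None):
            raise ValueError("need either a simulation config or expression+clinical paths")

    def provenance(self) -> dict:
        payload = {
            "seed": self.seed,
            "cutoff": self.cutoff,
            "rescreen": self.rescreen,
            "predictors": list(self.predictors),
            "simulation": vars(self.simulation) if self.simulation else None,
        }
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
        return {"config_sha256": digest, "seed": self.seed, "version": __version__}


def validate_inputs(
    expression_samples,
    clinical_samples,
    tcr_samples=None,
    marker_samples=None,
) -> dict:
    """Cross-table sample-id alignment report: shared ids, per-table orphans,
    duplicated ids.  Reporting only."""
    tables = {"expression": list(expression_samples), "clinical": list(clinical_samples)}
    if tcr_samples is not None:
        tables["tcr"] = list(tcr_samples)
    if marker_samples is not None:
        tables["markers"] = list(marker_samples)
    sets = {name: set(ids) for name, ids in tables.items()}
    shared = set.intersection(*sets.values()) if sets else set()
    report = {
        "shared": sorted(shared),
        "orphans": {name: sorted(ids - shared) for name, ids in sets.items() if ids - shared},
        "duplicates": {
            name: sorted({x for x in ids if ids.count(x) > 1})
            for name, ids in tables.items()
            if len(set(ids)) != len(ids)
        },
    }
    return report


def _response_rates(category: pd.Series, response: pd.Series) -> dict:
    rates = {}
    for cat in ("positive", "neutral", "negative"):
        mask = category == cat
        n = int(mask.sum())
        rates[cat] = {
            "n": n,
            "responders": int(response[mask].sum()) if n else 0,
            "rate": float(response[mask].mean()) if n else None,
        }
    return rates


def _predictor_values(name: str, tse_frame: pd.DataFrame, clinical: pd.DataFrame) -> pd.Series:
    if name in ("tse", "global_T", "global_S"):
        return tse_frame[name if name != "tse" else "tse"]
    if name == "tmb":
        return clinical["tmb"]
    if name == "apobec":
        return clinical["apobec_E"]
    raise KeyError(name)


def evaluate(
    tse_frame: pd.DataFrame,
    clinical: pd.DataFrame,
    predictors=("tse", "tmb", "apobec"),
) -> dict:
    """Evaluation block: response rates by category, Fisher positive-vs-negative,
    ROC/AUC per predictor with pairwise DeLong tests, survival summaries."""
    samples = tse_frame.index.intersection(clinical.index)
    tse_frame = tse_frame.loc[samples]
    clinical = clinical.loc[samples]
    response = clinical["response"].astype(int)
    category = tse_frame["category"]

    summary: dict = {"n_samples": int(len(samples))}
    summary["category_counts"] = {str(k): int(v) for k, v in category.value_counts().items()}
    summary["response_rates_by_category"] = _response_rates(category, response)

    pos, neg = category == "positive", category == "negative"
    if pos.any() and neg.any():
        table = [
            [int(response[pos].sum()), int((1 - response[pos]).sum())],
            [int(response[neg].sum()), int((1 - response[neg]).sum())],
        ]
        odds, p = fisher_exact(table)
        summary["fisher_positive_vs_negative"] = {
            "table": table,
            "odds_ratio": None if not np.isfinite(odds) else odds,
            "p": p,
            "significant_at_0.05": bool(p < 0.05),
        }
    else:
        summary["fisher_positive_vs_negative"] = None

    label = response.to_numpy()
    roc_block: dict = {}
    values: dict[str, np.ndarray] = {}
    if label.min() != label.max():
        for name in predictors:
            vals = _predictor_values(name, tse_frame, clinical).to_numpy(dtype=float)
            values[name] = vals
            res = roc_auc(vals, label)
            roc_block[name] = {"auc": res.auc, "delong_variance": res.variance}
        delong_block = {}
        names = list(predictors)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                auc_a, auc_b, z, p = delong_test(values[a], values[b], label)
                delong_block[f"{a}_vs_{b}"] = {"auc_a": auc_a, "auc_b": auc_b, "z": z, "p": p}
        summary["roc"] = roc_block
        summary["delong"] = delong_block
    else:
        summary["roc"] = None
        summary["delong"] = None

    survival_block: dict = {}
    for endpoint in ("os", "pfs"):
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        if tcol not in clinical.columns:
            continue
        times = clinical[tcol].to_numpy(dtype=float)
        events = clinical[ecol].to_numpy(dtype=int)
        block: dict = {}
        if len(category.unique()) >= 2 and events.sum() > 0:
            stat, p = logrank(times, events, category.to_numpy())
            block["logrank_by_category"] = {"statistic": stat, "p": p}
            if pos.any() and neg.any() and events[pos | neg].sum() > 0:
                sub = pos | neg
                cox = cox_fit(
                    times[sub],
                    events[sub],
                    pd.DataFrame({"positive": pos[sub].astype(float).to_numpy()}),
                )
                row = cox.iloc[0]
                block["cox_positive_vs_negative"] = {
                    "hr": float(row["hr"]),
                    "hr_lower": float(row["hr_lower"]),
                    "hr_upper": float(row["hr_upper"]),
                    "p": float(row["p"]),
                }
        cov = pd.DataFrame({name: values[name] for name in values}) if values else None
        if cov is not None and events.sum() > 0:
            cox = cox_fit(times, events, cov)
            block["cox_continuous"] = {
                name: {"hr": float(r["hr"]), "p": float(r["p"])} for name, r in cox.iterrows()
            }
        survival_block[endpoint] = block
    summary["survival"] = survival_block
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Run the pipeline and write ``tse.tsv``, ``summary.json`` (and, for
    simulated inputs, the cohort files) under ``config.out_dir``.

    Deterministic given fixed inputs and seed.  On stage failure the
    partially-written output directory content from this run is removed and
    a :class:`PipelineError` naming the stage is raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        stage = "inputs"
        t0 = time.perf_counter()
        if config.simulation is not None:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = SimulationConfig(**{**vars(sim), "seed": config.seed})
            cohort = generate_cohort(sim)
            paths = write_cohort(cohort, out_dir / "inputs")
            written.extend(paths.values())
            expr, sigs, clinical = cohort.expression, cohort.signatures, cohort.clinical
            markers = cohort.markers
        else:
            expr = read_expression_matrix(config.expression_path)
            sigs = read_gmt(config.gmt_path)
            clinical = pd.read_csv(config.clinical_path, sep="\t", index_col=0)
            markers = pd.read_csv(config.markers_path, index_col=0) if config.markers_path else None
        timings[stage] = time.perf_counter() - t0

        stage = "validate"
        t0 = time.perf_counter()
        validation = validate_inputs(
            expr.sample_ids,
            clinical.index.tolist(),
            marker_samples=markers.index.tolist() if markers is not None else None,
        )
        timings[stage] = time.perf_counter() - t0

        stage = "score"
        t0 = time.perf_counter()
        rescreen_labels = None
        if config.rescreen:
            shared = [s for s in expr.sample_ids if s in clinical.index]
            rescreen_labels = clinical.loc[shared, "response"].astype(int).to_numpy()
        result = score_cohort(
            expr,
            sigs,
            cutoff=config.cutoff,
            rescreen_response=rescreen_labels,
            auc_threshold=config.auc_threshold,
        )
        tse_frame = result.to_frame()
        tse_path = out_dir / "tse.tsv"
        tse_frame.to_csv(tse_path, sep="\t", float_format="%.10g")
        written.append(tse_path)
        timings[stage] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        covariates = {}
        if "tmb" in clinical.columns:
            covariates["tmb_class"] = clinical["tmb"].map(classify_tmb)
        if {"apobec_E", "apobec_detected"} <= set(clinical.columns):
            covariates["apobec_high"] = [
                apobec_high_vs_nonhigh(e, bool(d))
                for e, d in zip(clinical["apobec_E"], clinical["apobec_detected"])
            ]
        timings[stage] = time.perf_counter() - t0

        stage = "evaluate"
        t0 = time.perf_counter()
        summary = {
            "provenance": config.provenance(),
            "validation": validation,
            "evaluation": evaluate(tse_frame, clinical, predictors=config.predictors),
        }
        if markers is not None:
            protein = score_marker_table(markers)
            protein_path = out_dir / "protein.tsv"
            protein.to_csv(protein_path, sep="\t", float_format="%.10g")
            written.append(protein_path)
            joint = protein["tse_protein"].reindex(tse_frame.index).astype(float)
            valid = joint.notna()
            if valid.sum() >= 3:
                from scipy import stats as sps

                rho, p = sps.spearmanr(tse_frame.loc[valid, "tse"], joint[valid])
                summary["protein_rna_spearman"] = {"rho": float(rho), "p": float(p)}
        timings[stage] = time.perf_counter() - t0

        stage = "write"
        summary_path = out_dir / "summary.json"
        summary_path.write_text(json.dumps(summary, sort_keys=True, indent=2, default=float) + "\n")
        written.append(summary_path)
        log_path = out_dir / "run.log"
        log_path.write_text(
            "".join(f"{name}\t{seconds:.3f}s\n" for name, seconds in timings.items())
        )
        return summary
    except Exception as exc:
        for path in written:
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
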