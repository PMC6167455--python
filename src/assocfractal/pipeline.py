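"""End-to-end pipeline: chains + vectors + scores → analysis report.

Sequences the whole analysis: clean chains into SmD series, handle
missing values, zero-pad, estimate temporal structure (PSD slope, DFA
exponent, sample entropy), join with per-participant creativity scores,
and run the correlation table plus the two confirmatory inverted-U
regressions (creativity, novelty) and the response-time regression.
Every exclusion (too-short series, all-missing, unmatched participant)
is logged with its reason; the report echoes the effective configuration
so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .complexity import classify_structure, estimate_series
from .errors import EmptySeriesError, InvalidInputError
from .prep import (
    AssociationChain,
    chain_to_series,
    handle_missing,
    read_chains_csv,
    write_oov_report,
    zero_pad,
)
from .space import SemanticSpace, read_vectors
from .stats import InvertedUModel, correlation_table, rt_smd_regression

logger = logging.getLogger("assocfractal")

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "run_pipeline_files"]

#: Fit R² below which a log-log fit is flagged as a fractality caveat.
FIT_R2_WARN = 0.8

SCORE_COLUMNS = [
    "aut_creativity",
    "aut_novelty",
    "aut_usefulness",
    "aut_fluency",
    "crat",
    "caq",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that determines a pipeline run (echoed in the report)."""

    missing_policy: str = "drop"
    min_series_length: int = 32
    pad_dfa: bool = False
    drop_high_freq_fraction: float = 0.5
    dfa_min_window: int = 4
    dfa_n_scales: int = 10
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    center_predictors: bool = False
    holm: bool = False

    def __post_init__(self):
        if self.min_series_length < 32:
            raise InvalidInputError(
                "min_series_length below 32 would feed the estimators series "
                "they cannot resolve"
            )


@dataclass
class AnalysisReport:
    """Structured result of one pipeline run."""

    estimates: pd.DataFrame
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    regressions: dict
    rt_regression: dict
    exclusions: list[dict]
    config: dict
    n_analyzed: int
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "n_analyzed": self.n_analyzed,
            "exclusions": self.exclusions,
            "descriptives": json.loads(
                self.descriptives.to_json(orient="index", double_precision=10)
            ),
            "estimates": json.loads(
                self.estimates.to_json(orient="records", double_precision=10)
            ),
            "correlations": json.loads(
                self.correlations.to_json(orient="records", double_precision=10)
            ),
            "regressions": self.regressions,
            "rt_regression": self.rt_regression,
        }

    def write(self, out_dir: str | Path) -> None:
        """Write estimates.tsv, correlations.tsv, regression.json,
        report.json and exclusions.log into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
        self.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
        with (out / "regression.json").open("w", encoding="utf-8") as fh:
            json.dump(
                {"models": self.regressions, "rt_regression": self.rt_regression},
                fh,
                indent=1,
            )
        with (out / "report.json").open("w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
        with (out / "exclusions.log").open("w", encoding="utf-8") as fh:
            for exc in self.exclusions:
                fh.write(f"{exc['participant_id']}\t{exc['reason']}\n")


def run_pipeline(
    chains: list[AssociationChain],
    space: SemanticSpace,
    scores: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> AnalysisReport:
    """Run the full analysis on in-memory inputs."""
    scores = scores.copy()
    scores["participant_id"] = scores["participant_id"].astype(str)
    score_ids = set(scores["participant_id"])
    chain_ids = {c.participant_id for c in chains}

    exclusions: list[dict] = []
    for pid in sorted(score_ids - chain_ids):
        exclusions.append({"participant_id": pid, "reason": "no_chain"})
        logger.warning("participant %s: scores without chain, excluded", pid)

    rows = []
    for chain in sorted(chains, key=lambda c: c.participant_id):
        pid = chain.participant_id
        if pid not in score_ids:
            exclusions.append({"participant_id": pid, "reason": "no_scores"})
            logger.warning("participant %s: chain without scores, excluded", pid)
            continue
        try:
            series = chain_to_series(chain, space)
            series = handle_missing(series, config.missing_policy)
        except (EmptySeriesError, InvalidInputError) as err:
            exclusions.append({"participant_id": pid, "reason": str(err)})
            logger.warning("participant %s excluded: %s", pid, err)
            continue
        if series.n_observed < config.min_series_length:
            exclusions.append(
                {
                    "participant_id": pid,
                    "reason": f"series too short ({series.n_observed} < "
                    f"{config.min_series_length})",
                }
            )
            logger.warning(
                "participant %s excluded: %d observed values", pid, series.n_observed
            )
            continue
        padded = zero_pad(series)
        est = estimate_series(
            padded.values,
            unpadded=series.values,
            drop_high_freq_fraction=config.drop_high_freq_fraction,
            dfa_kwargs={
                "min_window": config.dfa_min_window,
                "n_scales": config.dfa_n_scales,
            },
            sampen_m=config.sampen_m,
            sampen_r_factor=config.sampen_r_factor,
            pad_dfa=config.pad_dfa,
        )
        for name, r2 in (("PSD", est.psd_fit_r2), ("DFA", est.dfa_fit_r2)):
            if r2 < FIT_R2_WARN:
                logger.warning(
                    "participant %s: %s log-log fit R^2 = %.2f < %.2f — "
                    "scaling may not be fractal",
                    pid,
                    name,
                    r2,
                    FIT_R2_WARN,
                )
        rows.append(
            {
                "participant_id": pid,
                "n_used": series.n_observed,
                "padded_length": padded.padded_length,
                "psd_slope": est.psd_slope,
                "psd_fit_r2": est.psd_fit_r2,
                "dfa_alpha": est.dfa_alpha,
                "dfa_fit_r2": est.dfa_fit_r2,
                "sample_entropy": est.sample_entropy,
                "structure_label": classify_structure(est, basis="dfa").label,
                "mean_smd": float(np.nanmean(series.values)),
                "mean_rt": float(np.mean(chain.response_times))
                if chain.response_times
                else np.nan,
            }
        )
    if not rows:
        raise InvalidInputError("zero analyzable participants")
    estimates = pd.DataFrame(rows)

    table = estimates.merge(scores, on="participant_id", how="inner")
    numeric_cols = SCORE_COLUMNS + [
        "psd_slope",
        "dfa_alpha",
        "sample_entropy",
        "mean_smd",
        "mean_rt",
    ]
    present = [c for c in numeric_cols if c in table.columns]
    # +inf sample entropy (no long-template matches) would poison the
    # moments; descriptives are over the finite values
    desc = (
        table[present]
        .apply(pd.to_numeric)
        .replace([np.inf, -np.inf], np.nan)
        .agg(["mean", "std", "min", "max"])
        .T
    )
    desc.columns = ["mean", "sd", "min", "max"]

    corr_cols = [c for c in SCORE_COLUMNS if c in table.columns] + ["mean_smd"]
    correlations = correlation_table(table, corr_cols, holm=config.holm)

    regressions = {}
    for outcome in ("aut_creativity", "aut_novelty"):
        if outcome in table.columns:
            result = InvertedUModel.from_dataframe(
                table, outcome=outcome, center=config.center_predictors
            ).fit()
            regressions[outcome] = result.to_dict()

    if table["mean_rt"].notna().sum() >= 3:
        rt_reg = rt_smd_regression(table["mean_rt"], table["mean_smd"]).to_dict()
    else:
        rt_reg = {"note": "response times absent; regression skipped"}

    return AnalysisReport(
        estimates=estimates,
        descriptives=desc,
        correlations=correlations,
        regressions=regressions,
        rt_regression=rt_reg,
        exclusions=exclusions,
        config=asdict(config),
        n_analyzed=len(table),
    )


def run_pipeline_files(
    chains_path: str | Path,
    vectors_path: str | Path,
    scores_path: str | Path,
    out_dir: str | Path | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> AnalysisReport:
    """Run the analysis from the on-disk file formats.

    Also writes the out-of-vocabulary report when ``out_dir`` is given.
    """
    chains = read_chains_csv(chains_path)
    space = read_vectors(vectors_path)
    scores = pd.read_csv(scores_path, dtype={"participant_id": str})
    report = run_pipeline(chains, space, scores, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_oov_report(chains, space, out / "oov_report.tsv")
        report.write(out)
    return report
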