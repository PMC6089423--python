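"""End-to-end pipeline orchestration with a run log.

One call executes clean → bootstrap structure learning → arc averaging
→ CPT fitting → component summary, and (optionally) writes every
artifact plus a run log embedding the full configuration actually
used. Given the same configuration and seed the artifact bytes are
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as enio
from .averaging import (ArcStrengthTable, AveragedNetwork, arc_strengths,
                        averaged_network, bootstrap_networks,
                        significance_threshold)
from .cleaning import apply_eligibility, recode_missing, select_variables, variable_report
from .encode import EncodedTable
from .inference import ComponentSummary, FittedNetwork, components, fit_cpts
from .metadata import VariableMeta, analysis_variables
from .sentinels import DEFAULT_MISSING_CODES
from .structure import ConstraintSet, LearnConfig, layer_blacklist


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of a pipeline run, with documented defaults."""

    alpha: float = 0.05                  # CI-test significance level
    score_type: str = "bic"              # bic | bdeu
    test: str = "g2"                     # g2 | x2
    max_cond: int = 3                    # largest MMPC conditioning set
    n_boot: int = 200                    # bootstrap replicates
    threshold: float | None = None       # None = L1-CDF estimator
    seed: int = 0
    pseudocount: float = 0.0
    ineligible_as_level: bool = False    # promote INELIGIBLE to a level
    missing_codes: tuple[str, ...] = tuple(sorted(DEFAULT_MISSING_CODES))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def learn_config(self) -> LearnConfig:
        return LearnConfig(alpha=self.alpha, max_cond=self.max_cond,
                           test=self.test, score_type=self.score_type)


@dataclass
class PipelineResult:
    config: RunConfig
    clean_table: pd.DataFrame
    report: pd.DataFrame
    constraints: ConstraintSet
    dags: list
    strengths: ArcStrengthTable
    threshold: float
    averaged: AveragedNetwork
    fitted: FittedNetwork
    summary: ComponentSummary
    run_log: dict = field(default_factory=dict)


def run_pipeline(raw: pd.DataFrame, meta: Sequence[VariableMeta],
                 config: RunConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis and optionally write all artifacts.

    Artifacts written under ``out_dir``: clean.csv, report.tsv,
    strengths/arcs.tsv, averaged.json (DAG), fitted.json (CPTs),
    components.json, network.dot, network.graphml and run_log.json.
    Any stage error aborts with the stage name attached.
    """
    config = config or RunConfig()
    log: dict = {"config": config.to_dict(), "stages": []}

    def stage(name: str):
        log["stages"].append(name)
        return name

    try:
        stage("clean")
        cleaned = select_variables(
            apply_eligibility(
                recode_missing(raw, config.missing_codes), meta
            ),
            meta,
        )
        report = variable_report(cleaned)
    except Exception as exc:
        raise StageError("clean", exc) from exc

    analysis_meta = analysis_variables(list(meta))
    constraints = layer_blacklist(meta)

    try:
        stage("learn/bootstrap")
        enc = EncodedTable.from_frame(
            cleaned, analysis_meta,
            ineligible_as_level=config.ineligible_as_level,
        )
        dags = bootstrap_networks(
            enc, analysis_meta, constraints, config.learn_config(),
            n_boot=config.n_boot, seed=config.seed,
        )
    except Exception as exc:
        raise StageError("learn/bootstrap", exc) from exc

    try:
        stage("average")
        strengths = arc_strengths(dags)
        if config.threshold is None:
            threshold, _ = significance_threshold(strengths)
        else:
            threshold = float(config.threshold)
        averaged = averaged_network(strengths, threshold, constraints)
    except Exception as exc:
        raise StageError("average", exc) from exc

    try:
        stage("fit")
        fitted = fit_cpts(cleaned, averaged.dag, analysis_meta,
                          pseudocount=config.pseudocount)
        summary = components(averaged.dag)
    except Exception as exc:
        raise StageError("fit", exc) from exc

    log["threshold"] = threshold
    log["n_arcs"] = averaged.dag.number_of_edges()
    log["n_networks"] = summary.n_networks
    result = PipelineResult(
        config=config, clean_table=cleaned, report=report,
        constraints=constraints, dags=dags, strengths=strengths,
        threshold=threshold, averaged=averaged, fitted=fitted,
        summary=summary, run_log=log,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir), meta)
    return result


def _write_artifacts(result: PipelineResult, out: Path,
                     meta: Sequence[VariableMeta]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    enio.write_survey(result.clean_table, out / "clean.csv")
    report = result.report.copy()
    report["level_frequencies"] = report["level_frequencies"].map(
        lambda d: json.dumps(d, sort_keys=True)
    )
    report.to_csv(out / "report.tsv", sep="\t")
    enio.write_arcs(result.averaged, out / "arcs.tsv")
    enio.write_dag(result.averaged.dag, out / "averaged.json")
    (out / "fitted.json").write_text(enio.fitted_to_json(result.fitted))
    (out / "components.json").write_text(json.dumps({
        "components": [list(c) for c in result.summary.components],
        "networks": result.summary.n_networks,
        "sizes": list(result.summary.sizes),
        "isolated": list(result.summary.isolated),
    }, indent=1))
    enio.export_network(result.averaged, out / "network.dot", "dot",
                        result.clean_table, list(meta))
    enio.export_network(result.averaged, out / "network.graphml", "graphml",
                        result.clean_table, list(meta))
    (out / "run_log.json").write_text(json.dumps(result.run_log, indent=1))


def artifact_hashes(out_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every artifact file (for reproducibility checks)."""
    out = Path(out_dir)
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir()) if p.is_file()
    }
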