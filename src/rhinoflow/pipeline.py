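"""End-to-end pipeline runs: stage chaining, artifacts, provenance.

Each mode executes a fixed stage chain and writes CSV/JSON artifacts into
the configured output directory.  Every artifact set includes a provenance
record (config hash, seed, package version, model conventions) so a run can
be reproduced byte-for-byte from its configuration; logs go to stderr with
ISO-8601 timestamps and never into the artifacts.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd

from .cohort import generate_cohort
from .config import RunConfig, config_hash, config_to_doc, load_airway_file
from .errors import ConfigError
from .geometry import SubjectState, default_template
from .protocol import extract_subject_metrics, run_subject_protocol
from .stats import load_reference_cohort, reproduce_reference_tables, summarize_cohort
from .tables import CohortTable

__all__ = ["run_pipeline", "configure_logging"]

log = logging.getLogger("rhinoflow")


def configure_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S%z")
    )
    root = logging.getLogger("rhinoflow")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


def _provenance(config: RunConfig) -> dict:
    from . import __version__

    return {
        "config_hash": config_hash(config),
        "config": config_to_doc(config),
        "seed": config.seed,
        "package_version": __version__,
        "conventions": {
            "pressure_drop_model": "fully developed laminar viscous (minor losses off)",
            "saturation_vapor_pressure": "Arden Buck over liquid water",
            "sd_convention_tables": "SAMPLE",
            "two_sample_default": "WELCH",
        },
    }


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _write_summary(outdir: Path, table: CohortTable) -> list[Path]:
    summary = summarize_cohort(table)
    v_path = outdir / "summary_variables.csv"
    c_path = outdir / "summary_correlations.csv"
    summary.variables.to_csv(v_path)
    summary.correlations.to_csv(c_path, index=False)
    m_path = outdir / "summary_metadata.json"
    _write_json(m_path, summary.metadata)
    return [v_path, c_path, m_path]


def run_pipeline(config: RunConfig) -> dict[str, list[str]]:
    """Execute the configured mode; returns the artifact paths per stage."""
    config.validate()
    configure_logging(config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, list[str]] = {}
    log.info("run start: mode=%s seed=%d hash=%s", config.mode, config.seed, config_hash(config))

    prov_path = outdir / "provenance.json"
    _write_json(prov_path, _provenance(config))
    artifacts["provenance"] = [str(prov_path)]

    if config.mode == "SYNTHETIC_COHORT":
        log.info("stage: generate_cohort (n=%d)", config.cohort.n_subjects)
        table = generate_cohort(config.cohort, config.ambient)
        cohort_csv = outdir / "cohort.csv"
        table.write(cohort_csv, outdir / "cohort_provenance.json")
        artifacts["cohort"] = [str(cohort_csv), str(outdir / "cohort_provenance.json")]
        log.info("stage: summarize_cohort")
        artifacts["summary"] = [str(p) for p in _write_summary(outdir, table)]

    elif config.mode == "REFERENCE_FIXTURES":
        log.info("stage: load_reference_cohort")
        table = load_reference_cohort()
        ref_csv = outdir / "reference_cohort.csv"
        table.write(ref_csv)
        artifacts["cohort"] = [str(ref_csv)]
        log.info("stage: reproduce_reference_tables")
        report = reproduce_reference_tables()
        report_csv = outdir / "reference_check_report.csv"
        report.to_csv(report_csv, index=False)
        gating = report[report["gating"]]
        _write_json(
            outdir / "reference_check_report.json",
            {
                "checks_total": int(len(report)),
                "checks_gating": int(len(gating)),
                "checks_failed": int((~gating["passed"]).sum()),
                "all_gating_passed": bool(gating["passed"].all()),
            },
        )
        artifacts["report"] = [
            str(report_csv),
            str(outdir / "reference_check_report.json"),
        ]
        artifacts["summary"] = [str(p) for p in _write_summary(outdir, table)]

    elif config.mode == "SINGLE_SUBJECT":
        log.info("stage: build_models")
        if config.preop_file or config.postop_file:
            if not (config.preop_file and config.postop_file):
                raise ConfigError("SINGLE_SUBJECT needs both preop_file and postop_file")
            preop = load_airway_file(config.preop_file)
            postop = load_airway_file(config.postop_file)
        else:
            # symmetric template pair: a no-op surgery baseline
            preop = default_template("template", SubjectState.PREOP)
            postop = default_template("template", SubjectState.POSTOP)
        log.info("stage: run_subject_protocol")
        result = run_subject_protocol(
            preop, postop, config.ambient, target_flow=config.target_flow
        )
        rows = [
            extract_subject_metrics(result, SubjectState.PREOP).to_row(),
            extract_subject_metrics(result, SubjectState.POSTOP).to_row(),
        ]
        metrics_csv = outdir / "subject_metrics.csv"
        pd.DataFrame(rows).to_csv(metrics_csv, index=False)
        artifacts["metrics"] = [str(metrics_csv)]

    log.info("run complete: %d artifact groups", len(artifacts))
    return artifacts
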