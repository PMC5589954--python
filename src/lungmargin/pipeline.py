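"""End-to-end runs: simulate -> parse -> budget -> margins -> coverage -> stats.

Two entry modes:

* ``from-budget`` — start from per-patient error-budget and uncertainty
  tables (the bundled reference cohort by default) and compute margins and
  coverage; no logs involved.
* ``simulate`` — generate a synthetic cohort, write and re-parse its log
  bundles, build the full five-step budget per patient, then margins,
  coverage and the association battery.

Every run writes a manifest (parameter values, seed, SHA-256 of each output)
so identical configurations are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, datasets, synthetic
from .error_budget import compute_patient_budget, targeting_budget
from .log_io import AXES, parse_bundle
from .margins import (
    MarginParams,
    budget_margin_table,
    coverage_report,
    uncertainty_margin_table,
)

log = logging.getLogger("lungmargin")

DEFAULT_THRESHOLDS = (3.0, 4.0, 5.0)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "from-budget"            # "from-budget" | "simulate"
    output_dir: str | Path = "lungmargin_run"
    seed: int = 0
    thresholds: tuple = DEFAULT_THRESHOLDS
    margin_params: MarginParams = field(default_factory=MarginParams)
    budget_path: str | Path | None = None        # from-budget inputs
    uncertainty_path: str | Path | None = None
    n_patients: int = 22                         # simulate inputs
    n_fractions_range: tuple = (3, 5)
    duration_s: float = 1720.0
    make_plots: bool = False

    def validate(self) -> None:
        if self.mode not in ("from-budget", "simulate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        thr = [float(t) for t in self.thresholds]
        if any(t <= 0 for t in thr) or thr != sorted(thr):
            raise ValueError("thresholds must be positive and ascending")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, outputs: list[Path]) -> Path:
    manifest = {
        "parameters": {
            "mode": config.mode,
            "seed": config.seed,
            "thresholds": [float(t) for t in config.thresholds],
            "sigma_p": config.margin_params.sigma_p,
            "beta": config.margin_params.beta,
            "n_patients": config.n_patients,
            "n_fractions_range": list(config.n_fractions_range),
            "duration_s": config.duration_s,
        },
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def run_from_budget(config: RunConfig) -> dict:
    """Margins and coverage from budget/uncertainty tables (no logs)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    budget = (
        pd.read_csv(config.budget_path)
        if config.budget_path
        else datasets.load_reference_budget()
    )
    u_table = (
        pd.read_csv(config.uncertainty_path)
        if config.uncertainty_path
        else datasets.load_reference_uncertainty()
    )
    log.info("budget stage: %d patients", len(budget))
    m_table = budget_margin_table(budget, config.margin_params)
    u_margins = uncertainty_margin_table(u_table)
    margin_table = m_table.merge(u_margins, on="patient")
    cov = coverage_report(m_table, config.thresholds)
    log.info("margin stage: %d patients, coverage thresholds %s",
             len(m_table), list(config.thresholds))

    margins_path = outdir / "margin_table.csv"
    margin_table.round(4).to_csv(margins_path, index=False)
    cov_path = outdir / "coverage.json"
    cov_path.write_text(json.dumps(cov, indent=1, sort_keys=True))
    manifest = _write_manifest(outdir, config, [margins_path, cov_path])
    return {
        "margin_table": margin_table,
        "coverage": cov,
        "outputs": [margins_path, cov_path, manifest],
    }


def _roundtrip_bundles(patient: synthetic.PatientSim, workdir: Path) -> list:
    """Write one patient's bundles in the CSV dialects and parse them back."""
    bundles = []
    for truth, bundle in patient.fractions:
        d = workdir / patient.patient_id / bundle.fraction_id
        synthetic.write_bundle(bundle, d)
        bundles.append(
            parse_bundle(
                d,
                patient_id=bundle.patient_id,
                fraction_id=bundle.fraction_id,
                horizon_ms=bundle.predictor.horizon_ms,
                nominal_imaging_interval_s=truth.config.imaging_interval_s
                if truth.config else 40.0,
            )
        )
    return bundles


def run_simulated(config: RunConfig, *, roundtrip_logs: bool = False) -> dict:
    """Full pipeline on a synthetic cohort.

    With ``roundtrip_logs`` the bundles are serialized to the CSV dialects
    and re-parsed before analysis, exercising the writer/parser pair at the
    cost of disk traffic; the default analyses the in-memory bundles.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    base = synthetic.RespiratoryConfig(duration_s=config.duration_s, seed=config.seed)
    cohort = synthetic.simulate_cohort(
        n_patients=config.n_patients,
        n_fractions_range=tuple(config.n_fractions_range),
        base_config=base,
        seed=config.seed,
    )
    log.info("simulate stage: %d patients, %d fractions",
             len(cohort), sum(len(p.fractions) for p in cohort))

    e2e = datasets.synthetic_e2e_records()
    targeting = targeting_budget(e2e)

    budgets, frac_rows, meta_rows = [], [], []
    from .error_budget import correlation_error, prediction_error, motion_range
    from .log_io import gate_to_beam_on

    for patient in cohort:
        if roundtrip_logs:
            bundles = _roundtrip_bundles(patient, outdir / "logs")
        else:
            bundles = [b for _, b in patient.fractions]
        budget, series = compute_patient_budget(
            bundles, targeting=targeting, patient_id=patient.patient_id
        )
        budgets.append(budget)
        meta_rows.append(
            {
                "patient": patient.patient_id,
                "lobe": patient.lobe,
                "location": patient.location,
                "volume_cm3": patient.volume_cm3,
            }
        )
        for cs, ps, bundle in zip(
            series["correlation"], series["prediction"], bundles
        ):
            gated = gate_to_beam_on(bundle)
            row = {"patient": patient.patient_id, "fraction": cs.fraction_id}
            rng = motion_range(gated.modeler)
            for k, ax in enumerate(AXES):
                row[f"range_{ax}"] = float(rng[k])
                row[f"sd_corr_{ax}"] = float(np.std(cs.errors[:, k], ddof=1))
                row[f"sd_pred_{ax}"] = float(np.std(ps.errors[:, k], ddof=1))
            frac_rows.append(row)

    budget_df = pd.DataFrame([b.budget_row() for b in budgets])
    u_df = pd.DataFrame([b.uncertainty_row() for b in budgets])
    m_table = budget_margin_table(budget_df, config.margin_params)
    u_margins = uncertainty_margin_table(u_df)
    margin_table = m_table.merge(u_margins, on="patient")
    cov = coverage_report(m_table, config.thresholds)
    log.info("budget stage: %d patients analysed", len(budget_df))

    frac_df = cohort_stats.fraction_table(frac_rows)
    pat_df = cohort_stats.patient_table(
        budgets, metadata=pd.DataFrame(meta_rows), margins=margin_table
    )
    stats = cohort_stats.association_report(frac_df, pat_df)
    log.info("stats stage: %d fraction rows, %d patient rows",
             len(frac_df), len(pat_df))

    outputs = []
    for name, df in (
        ("budget_table.csv", budget_df),
        ("uncertainty_table.csv", u_df),
        ("margin_table.csv", margin_table),
        ("fraction_table.csv", frac_df),
        ("patient_table.csv", pat_df),
    ):
        p = outdir / name
        df.round(6).to_csv(p, index=False)
        outputs.append(p)
    cov_path = outdir / "coverage.json"
    cov_path.write_text(json.dumps(cov, indent=1, sort_keys=True))
    stats_path = outdir / "stats.json"
    stats_path.write_text(json.dumps(stats, indent=1, sort_keys=True))
    outputs += [cov_path, stats_path]

    if config.make_plots:
        from . import plots
        sample = cohort[0].fractions[0][1]
        outputs.append(plots.fraction_error_plot(sample, outdir / "fraction_errors.png"))
        outputs.append(
            plots.association_plot(frac_df, "range_si", "sd_corr_si",
                                   outdir / "range_vs_sd.png")
        )
    manifest = _write_manifest(outdir, config, outputs)
    return {
        "cohort": cohort,
        "budgets": budgets,
        "budget_table": budget_df,
        "uncertainty_table": u_df,
        "margin_table": margin_table,
        "coverage": cov,
        "fraction_table": frac_df,
        "patient_table": pat_df,
        "stats": stats,
        "outputs": outputs + [manifest],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Dispatch a run on its mode; see :class:`RunConfig`."""
    config.validate()
    if config.mode == "from-budget":
        return run_from_budget(config)
    return run_simulated(config)
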