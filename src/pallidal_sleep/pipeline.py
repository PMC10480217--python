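"""Subject-level and cohort-level orchestration.

``run_subject`` takes one subject's signals and dual hypnograms through the
full chain: staging consensus -> sleep parameters (incl. fragmentation and
RSWA) -> per-stage normalized spectra and band powers -> per-Hz beta-burst
statistics -> adaptive-stimulation simulation. ``run_cohort`` runs every
subject, pools envelopes for the cohort burst threshold, and computes the
group comparisons, correlation matrix, and clinical-style summaries.
All randomness is owned by the synthetic generator; given a fixed cohort
bundle the pipeline is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adbs, bursts, sleep_metrics, spectral, staging
from .containers import NREM_STAGES
from .synthetic import CohortBundle, SubjectData

logger = logging.getLogger("pallidal_sleep")


@dataclass
class RunConfig:
    """Every analysis parameter, overridable from a YAML config file."""

    seed: int = 0
    out_dir: str = "results"
    # spectral
    theta_band: tuple[float, float] = (4.0, 12.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    low_beta_band: tuple[float, float] = (13.0, 20.0)
    high_beta_band: tuple[float, float] = (20.0, 30.0)
    norm_ranges: tuple[tuple[float, float], ...] = ((2.0, 45.0), (55.0, 80.0))
    welch_nfft: int = 512
    # staging
    min_rem_epochs: int = 5
    # bursts
    burst_threshold_percentile: float = 75.0
    burst_min_duration: float = 0.1
    morlet_cycles: float = 10.0
    # controller
    controller_threshold_percentile: float = 50.0
    v_min: float = 0.0
    v_max: float = 3.0
    ramp_rate: float = 0.4
    sliding_window: float = 5.0
    sliding_step: float = 0.5
    smoothing_sigma: float = 5.0
    # toggles
    analyze_substages: bool = False
    run_adbs: bool = True
    run_bursts: bool = True

    def band_definition(self) -> spectral.BandDefinition:
        return spectral.BandDefinition(
            theta=spectral.Band(*self.theta_band),
            beta=spectral.Band(*self.beta_band),
            low_beta=spectral.Band(*self.low_beta_band, hi_inclusive=False),
            high_beta=spectral.Band(*self.high_beta_band),
            norm_ranges=tuple(tuple(r) for r in self.norm_ranges),
        )


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            values.update(yaml.safe_load(fh) or {})
    values.update(overrides)
    cfg = RunConfig()
    for k, v in values.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config key {k!r}")
        setattr(cfg, k, v)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


@dataclass
class SubjectReport:
    subject_id: str
    diagnosis: str
    agreement_fraction: float
    rem_eligible: bool
    sleep_parameters: dict[str, float]
    band_powers: dict[str, dict[str, float]]  # stage -> band -> %
    adjusted_beta: dict[str, float]  # stage -> 1/f-adjusted beta (log10 residual sum)
    burst: dict[str, bursts.BurstStats] = field(default_factory=dict)
    stim_on_pct: dict[str, float] = field(default_factory=dict)
    stage_signals: dict[str, np.ndarray] = field(default_factory=dict)
    consensus: staging.ConsensusHypnogram | None = None


def _concat_stage(epoched: staging.EpochedSignal, stage: str) -> np.ndarray:
    parts = epoched.epochs(stage)
    return np.concatenate(parts) if parts else np.empty(0)


def run_subject(subject: SubjectData, cfg: RunConfig | None = None) -> SubjectReport:
    """Full per-night analysis of one subject.

    REM-dependent outputs (REM spectra, REM bursts, REM stimulation time,
    RSWA) are reported as missing when the consensus hypnogram carries fewer
    than ``cfg.min_rem_epochs`` agreeing REM epochs.
    """
    cfg = cfg or RunConfig()
    bands = cfg.band_definition()
    ch = staging.consensus(subject.hypnogram, subject.hypnogram2)
    eligible = staging.rem_eligible(ch, cfg.min_rem_epochs)

    # Sleep parameters come from the primary (human-scored) hypnogram; the
    # consensus gates only which epochs enter the LFP analyses.
    h1 = staging.hypnogram_as_consensus(subject.hypnogram)
    params = sleep_metrics.parameters_with_extras(h1, subject.emg, h1 if eligible else None)
    epoched = staging.epoch_signal(subject.lfp, ch)

    stages = ("W", "NREM", "R") if eligible else ("W", "NREM")
    if cfg.analyze_substages:
        stages = stages + NREM_STAGES
    spectra = spectral.stage_spectra(epoched, stages, bands)
    powers = spectral.stage_band_powers(spectra, bands)

    adjusted: dict[str, float] = {}
    for stage, spec in spectra.items():
        try:
            fit = spectral.fit_aperiodic(spec)
            mask = bands.beta.mask(fit.freqs)
            adjusted[stage] = float(fit.residual_periodic[mask].sum())
        except ValueError:
            adjusted[stage] = np.nan

    report = SubjectReport(
        subject_id=subject.subject_id,
        diagnosis=subject.diagnosis,
        agreement_fraction=ch.agreement_fraction,
        rem_eligible=eligible,
        sleep_parameters=params.as_dict(),
        band_powers=powers,
        adjusted_beta=adjusted,
        consensus=ch,
    )
    for stage in stages:
        report.stage_signals[stage] = _concat_stage(epoched, stage)

    if cfg.run_bursts:
        for stage in ("W", "NREM", "R"):
            x = report.stage_signals.get(stage, np.empty(0))
            if stage == "R" and not eligible:
                continue
            if x.size >= subject.lfp.sample_rate * 30:
                stats, _ = bursts.analyze_recording(
                    x, subject.lfp.sample_rate, q=cfg.burst_threshold_percentile
                )
                report.burst[stage] = stats

    if cfg.run_adbs:
        series = adbs.sliding_beta(
            subject.lfp.data[0], subject.lfp.sample_rate,
            cfg.sliding_window, cfg.sliding_step, cfg.smoothing_sigma, bands,
        )
        trace_stages = ("W", "NREM", "R") if eligible else ("W", "NREM")
        wake_mask = adbs.stage_mask(series.times, ch, "W")
        if wake_mask.any():
            thr = adbs.awake_threshold(series.beta[wake_mask], cfg.controller_threshold_percentile)
            trace = adbs.simulate_controller(
                series,
                adbs.ControllerConfig(thr, cfg.v_min, cfg.v_max, cfg.ramp_rate),
            )
            for stage in trace_stages:
                report.stim_on_pct[stage] = adbs.stim_on_fraction(trace, ch, stage)
    return report


# --------------------------------------------------------------------------
# cohort level
# --------------------------------------------------------------------------


@dataclass
class CohortReport:
    subject_table: pd.DataFrame  # sleep params + band powers per subject
    group_tests: pd.DataFrame
    correlations: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame] | None
    summaries: pd.DataFrame
    burst_table: pd.DataFrame | None


def cohort_band_table(bundle: CohortBundle, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Per-subject stage band powers (light path without bursts/controller)."""
    cfg = cfg or RunConfig()
    light = RunConfig(**{**asdict(cfg), "run_bursts": False, "run_adbs": False})
    rows = []
    for s in bundle.subjects:
        rep = run_subject(s, light)
        row = {"subject_id": s.subject_id, "diagnosis": s.diagnosis, **s.clinical}
        for stage, pw in rep.band_powers.items():
            for band, v in pw.items():
                row[f"{band}_{stage}"] = v
        for stage, v in rep.adjusted_beta.items():
            row[f"adjbeta_{stage}"] = v
        row.update({k: v for k, v in rep.sleep_parameters.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def run_cohort(bundle: CohortBundle, cfg: RunConfig | None = None) -> CohortReport:
    """Cohort analysis: per-subject runs, pooled burst threshold, group stats."""
    from .stats import correlation_matrix, mann_whitney_u, table_summary, tidy_results

    cfg = cfg or RunConfig()
    reports = [run_subject(s, cfg) for s in bundle.subjects]

    rows = []
    for s, rep in zip(bundle.subjects, reports):
        row = {
            "subject_id": rep.subject_id, "diagnosis": rep.diagnosis,
            "agreement": rep.agreement_fraction, "rem_eligible": rep.rem_eligible,
            **rep.sleep_parameters,
        }
        for stage, pw in rep.band_powers.items():
            for band, v in pw.items():
                row[f"{band}_{stage}"] = v
        for stage, v in rep.adjusted_beta.items():
            row[f"adjbeta_{stage}"] = v
        for stage, v in rep.stim_on_pct.items():
            row[f"stim_on_{stage}"] = v
        row["psqi"] = s.clinical.get("psqi", np.nan)
        row["rbdsq"] = s.clinical.get("rbdsq", np.nan)
        row["motor_off"] = s.clinical.get("motor_off", np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)

    burst_table = None
    if cfg.run_bursts:
        # cohort threshold: pool envelopes over all subjects and stages
        pool, keyed = [], []
        for s, rep in zip(bundle.subjects, reports):
            for stage, x in rep.stage_signals.items():
                if stage in ("W", "NREM", "R") and x.size >= s.lfp.sample_rate * 30:
                    env = bursts.envelope_bank(x, s.lfp.sample_rate)
                    pool.append(env)
                    keyed.append((rep.subject_id, rep.diagnosis, stage, env))
        if pool:
            thr = bursts.cohort_threshold(pool, cfg.burst_threshold_percentile)
            brows = []
            for sid, diag, stage, env in keyed:
                per_bin = [
                    bursts.burst_stats(
                        bursts.detect_bursts(env[i], float(thr[i]), cfg.burst_min_duration,
                                             frequency_bin=f),
                        env.shape[-1] / bursts.BURST_RATE,
                    )
                    for i, f in enumerate(bursts.BETA_BIN_FREQS)
                ]
                stats = bursts.average_over_bins(per_bin)
                brows.append({
                    "subject_id": sid, "diagnosis": diag, "stage": stage,
                    "mean_duration": stats.mean_duration, "mean_auc": stats.mean_auc,
                    "density": stats.density,
                })
            burst_table = pd.DataFrame(brows)

    tests = {}
    pd_rows = table[table["diagnosis"] == "PD"]
    dy_rows = table[table["diagnosis"] == "dystonia"]
    if len(pd_rows) and len(dy_rows):
        for col in ("theta_W", "beta_W", "theta_NREM", "beta_NREM", "theta_R", "beta_R",
                    "adjbeta_W", "adjbeta_NREM", "adjbeta_R",
                    "TST", "SL", "RSL", "Rpct", "SE", "Sfrag", "RSWA"):
            if col not in table:
                continue
            x, y = pd_rows[col].dropna(), dy_rows[col].dropna()
            if len(x) and len(y):
                try:
                    tests[col] = mann_whitney_u(x, y)
                except ValueError:
                    logger.warning("comparison %s skipped (degenerate data)", col)
        if burst_table is not None:
            for stage in ("NREM", "R"):
                sub = burst_table[burst_table["stage"] == stage]
                x = sub[sub["diagnosis"] == "PD"]["mean_duration"].dropna()
                y = sub[sub["diagnosis"] == "dystonia"]["mean_duration"].dropna()
                if len(x) and len(y):
                    tests[f"burst_duration_{stage}"] = mann_whitney_u(x, y)
    else:
        logger.warning("a diagnosis group is empty; group comparisons skipped")
    group_tests = tidy_results(tests) if tests else pd.DataFrame()

    corr = None
    corr_cols = [c for c in ("beta_W", "beta_NREM", "beta_R", "psqi", "motor_off") if c in table]
    if len(pd_rows) >= 3 and corr_cols:
        corr = correlation_matrix(pd_rows[corr_cols])

    srows = []
    for col in ("TST", "SL", "Rpct", "SE", "Sfrag", "RSWA", "psqi"):
        if col not in table:
            continue
        for grp in ("PD", "dystonia"):
            sub = table.rename(columns={"diagnosis": "diagnosis"})
            med, iqr = table_summary(sub, col, grp)
            srows.append({"column": col, "group": grp, "median": med, "iqr": iqr})
    summaries = pd.DataFrame(srows)

    return CohortReport(table, group_tests, corr, summaries, burst_table)


def write_report(report: CohortReport, out_dir: str | Path) -> dict[str, str]:
    """Write report tables as CSV with a sha256 manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "subject_table.csv": report.subject_table,
        "group_tests.csv": report.group_tests,
        "summaries.csv": report.summaries,
    }
    if report.burst_table is not None:
        files["burst_table.csv"] = report.burst_table
    if report.correlations is not None:
        rho, p, flags = report.correlations
        files["correlation_rho.csv"] = rho
        files["correlation_p.csv"] = p
        files["correlation_flagged.csv"] = flags
    manifest = {}
    for name, df in files.items():
        path = out / name
        df.to_csv(path, index=name.startswith("correlation"))
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
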