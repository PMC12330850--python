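"""End-to-end orchestration: generate, preprocess, transform, infer, report.

``run_pipeline`` sequences the full analysis on a synthetic cohort (or on
user-supplied containers prepared the same way): trial schedules, epoched
EEG, SCADS screening with spline interpolation and trial rejection,
condition averaging (with the acquisition half-split and empty-cell
exclusion rule), CSD, spectral SNR at the fundamental and second harmonic
with occipital pooling, pupil and rating pipelines, repeated-measures
ANOVAs and post-hoc paired tests, Bayes-factor weight-model topographies,
and the design power simulation.  A single master seed fans out to
per-subject, per-stage substreams, so any stage can be reproduced in
isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import bayes, preprocess, pupil, spectral, stats
from .power import PowerSimConfig, PowerSimResult, analytic_power, simulate_power
from .schedule import CS_PLUS, generate_schedule
from .sensors import SensorNet, egi_hydrocel_129
from .synth import GenParams, generate_eeg_epochs, generate_pupil, generate_ratings

logger = logging.getLogger("ssvepgen")

# substream tags for the master-seed fan-out
_STREAM_SCHEDULE = {"acquisition": 31, "context": 32}

CS_OPPOSITE = -45


@dataclass
class RunConfig:
    """All pipeline parameters; defaults reproduce the study settings.

    7.5 Hz drive, -600..+3900 ms epochs, 40 Hz low-pass, SCADS z=3 with
    trial rejection above 20 bad sensors, CSD lambda=0.2, 600-3900 ms FFT
    window aligned to whole 7.5 Hz cycles, +/-2..4 noise bins, Oz+7
    occipital pool, alpha=.05.
    """

    seed: int = 7
    n_subjects: int = 52
    n_per_cell: int = 18
    phases: tuple = ("acquisition", "context")
    gen: GenParams = None
    filter_cutoff_hz: float = 40.0
    filter_order: int = 4
    scads_z: float = 3.0
    scads_max_bad: int = 20
    csd_lambda: float = 0.2
    csd_m: int = 4
    csd_terms: int = 50
    spectral_window_ms: tuple = (600.0, 3900.0)
    align_cycles_to_hz: float = 7.5
    frequencies: tuple = (7.5, 15.0)
    pupil_max_missing: float | None = None
    bayes_sensors: str = "all"  # or "pool"
    bayes_nodes: int = 64
    alpha: float = 0.05
    power: PowerSimConfig = None

    def __post_init__(self):
        if self.gen is None:
            self.gen = GenParams(seed=self.seed)
        elif isinstance(self.gen, dict):
            self.gen = GenParams(**self.gen)
        if self.power is None:
            self.power = PowerSimConfig(seed=self.seed)
        elif isinstance(self.power, dict):
            self.power = PowerSimConfig(**self.power)
        self.phases = tuple(self.phases)
        self.frequencies = tuple(float(f) for f in self.frequencies)
        self.spectral_window_ms = tuple(self.spectral_window_ms)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gen"] = asdict(self.gen)
        d["power"] = self.power.to_dict()
        for key in ("phases", "frequencies", "spectral_window_ms"):
            d[key] = list(d[key])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunReport:
    """Structured outputs of one pipeline run."""

    config: RunConfig
    snr_table: pd.DataFrame
    pupil_table: pd.DataFrame
    rating_tables: dict
    anovas: dict  # (phase, measure) -> AnovaResult
    ttests: dict  # label -> TTestResult
    bf_map: bayes.BFMap | None
    bf_pool: dict
    power: PowerSimResult
    retention: pd.DataFrame
    excluded_subjects_acquisition: tuple
    summary: dict

    def save(self, out_dir) -> dict:
        """Write all result tables plus a manifest; returns the manifest."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        manifest = {}

        def _write_df(name, df):
            path = os.path.join(out_dir, name)
            df.to_csv(path, index=False, float_format="%.10g")
            manifest[name] = {"rows": int(len(df))}

        _write_df("snr_table.csv", self.snr_table)
        _write_df("pupil_responses.csv", self.pupil_table)
        for phase, df in self.rating_tables.items():
            _write_df(f"ratings_{phase}.csv", df)
        anova_rows = []
        for (phase, measure), res in self.anovas.items():
            frame = res.to_frame()
            frame.insert(0, "phase", phase)
            frame.insert(1, "measure", measure)
            anova_rows.append(frame)
        _write_df("anovas.csv", pd.concat(anova_rows, ignore_index=True))
        tt_rows = [
            {"contrast": k, "t": v.t, "df": v.df, "p": v.p, "d": v.d,
             "d_ci_lo": v.d_ci[0], "d_ci_hi": v.d_ci[1]}
            for k, v in self.ttests.items()
        ]
        _write_df("ttests.csv", pd.DataFrame(tt_rows))
        if self.bf_map is not None:
            _write_df("bf_topography.csv", self.bf_map.table)
        with open(os.path.join(out_dir, "bf_pool.json"), "w") as fh:
            json.dump(self.bf_pool, fh, indent=1)
        manifest["bf_pool.json"] = {}
        with open(os.path.join(out_dir, "power.json"), "w") as fh:
            json.dump(self.power.to_dict(), fh, indent=1)
        manifest["power.json"] = {}
        _write_df("retention.csv", self.retention)
        self.config.to_yaml(os.path.join(out_dir, "run_config.yaml"))
        manifest["run_config.yaml"] = {}
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(self.summary, fh, indent=1)
        manifest["summary.json"] = {}
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest


def _assign_halves(labels: pd.DataFrame) -> pd.Series:
    n = len(labels)
    first = int(np.ceil(n / 2))
    return pd.Series(np.where(np.arange(n) < first, "1", "2"))


def _process_subject_eeg(config, net, phase, subject):
    """One subject's EEG chain: generate -> filter -> screen -> average -> CSD -> SNR."""
    sched = generate_schedule(
        phase,
        seed=[config.seed, subject, _STREAM_SCHEDULE[phase]],
        n_per_cell=config.n_per_cell,
    )
    epochs = generate_eeg_epochs(sched, config.gen, net, subject)
    epochs = preprocess.lowpass_filter(
        epochs, config.filter_cutoff_hz, config.filter_order
    )
    report = preprocess.scads_screen(
        epochs, net, z_threshold=config.scads_z,
        max_bad_sensors=config.scads_max_bad,
    )
    epochs = preprocess.interpolate_sensors(epochs, report, net)

    excluded = False
    if phase == "acquisition":
        epochs, excluded = preprocess.split_halves_and_screen(
            epochs, report.rejected_trials
        )
        group = ("orientation_deg", "half")
    else:
        group = ("orientation_deg", "context")
    clean = epochs.drop_trials(report.rejected_trials)
    avg = preprocess.average_conditions(clean, group)
    csd = spectral.csd_transform(
        avg, net, lam=config.csd_lambda, m=config.csd_m,
        n_terms=config.csd_terms,
    )
    snr = spectral.extract_snr_table(
        csd, net, subject, frequencies=config.frequencies,
        window_ms=config.spectral_window_ms,
        align_cycles_to_hz=config.align_cycles_to_hz,
    )
    if phase == "acquisition":
        snr = snr.rename(columns={"context": "half"})
    snr.insert(1, "phase", phase)
    retention = 1.0 - report.fraction_rejected
    logger.info(
        "subject %d %s: %d trials, retained %.1f%%, excluded=%s",
        subject, phase, len(sched), 100 * retention, excluded,
    )
    return snr, retention, excluded, sched


def _process_subject_pupil(config, subject, phase, sched):
    traces = generate_pupil(sched, config.gen, subject)
    if phase == "acquisition":
        traces.labels["half"] = _assign_halves(traces.labels).to_numpy()
    corrected, responses = pupil.preprocess_pupil(
        traces, max_missing_fraction=config.pupil_max_missing
    )
    df = corrected.labels.copy()
    df["response_mm"] = responses
    group = ["orientation_deg", "half" if phase == "acquisition" else "context"]
    out = df.groupby(group)["response_mm"].mean().reset_index()
    out.insert(0, "subject", subject)
    out.insert(1, "phase", phase)
    return out


def _posthoc(table, dv, cond_col, cond_val, alpha):
    """Paired CS+ vs CS-45 test within one condition level."""
    sub = table[table[cond_col] == cond_val] if cond_col else table
    wide = sub.pivot_table(index="subject", columns="orientation_deg",
                           values=dv, aggfunc="mean")
    return stats.paired_t(wide[CS_PLUS].to_numpy(), wide[CS_OPPOSITE].to_numpy())


def run_pipeline(config: RunConfig, net: SensorNet | None = None) -> RunReport:
    """Execute the full analysis; deterministic for a fixed config seed."""
    if net is None:
        net = egi_hydrocel_129()
    snr_rows, pupil_rows, retention_rows = [], [], []
    excluded_acq = []
    for subject in range(config.n_subjects):
        for phase in config.phases:
            snr, retention, excluded, sched = _process_subject_eeg(
                config, net, phase, subject
            )
            snr_rows.append(snr)
            retention_rows.append(
                {"subject": subject, "phase": phase, "retained": retention}
            )
            if phase == "acquisition" and excluded:
                excluded_acq.append(subject)
            pupil_rows.append(
                _process_subject_pupil(config, subject, phase, sched)
            )
    snr_table = pd.concat(snr_rows, ignore_index=True)
    pupil_table = pd.concat(pupil_rows, ignore_index=True)
    retention = pd.DataFrame(retention_rows)

    rating_tables = {}
    if "acquisition" in config.phases:
        rating_tables["acquisition"] = generate_ratings(
            config.gen, config.n_subjects, contexts=("none",)
        )
    if "context" in config.phases:
        rating_tables["context"] = generate_ratings(
            config.gen, config.n_subjects
        )

    anovas, ttests = {}, {}
    pooled = snr_table[snr_table["pooled"]]

    if "context" in config.phases:
        ctx_pool = pooled[pooled["phase"] == "context"]
        for f in config.frequencies:
            key = f"snr_{f:g}hz"
            sub = ctx_pool[ctx_pool["frequency_hz"] == f]
            anovas[("context", key)] = stats.rm_anova(
                sub, "snr", ["orientation_deg", "context"]
            )
            for ctx in ("aversive", "neutral"):
                ttests[f"context:{key}:cs+_vs_cs-45:{ctx}"] = _posthoc(
                    sub, "snr", "context", ctx, config.alpha
                )
        ctx_pupil = pupil_table[pupil_table["phase"] == "context"]
        anovas[("context", "pupil")] = stats.rm_anova(
            ctx_pupil, "response_mm", ["orientation_deg", "context"]
        )
        anovas[("context", "ratings")] = stats.rm_anova(
            rating_tables["context"], "rating", ["orientation_deg", "context"]
        )

    if "acquisition" in config.phases:
        keep = [
            s for s in range(config.n_subjects) if s not in excluded_acq
        ]
        acq_pool = pooled[
            (pooled["phase"] == "acquisition")
            & pooled["subject"].isin(keep)
        ]
        for f in config.frequencies:
            key = f"snr_{f:g}hz"
            sub = acq_pool[acq_pool["frequency_hz"] == f]
            anovas[("acquisition", key)] = stats.rm_anova(
                sub, "snr", ["orientation_deg", "half"]
            )
            ttests[f"acquisition:{key}:cs+_vs_cs-45:half2"] = _posthoc(
                sub, "snr", "half", "2", config.alpha
            )
        acq_pupil = pupil_table[pupil_table["phase"] == "acquisition"]
        anovas[("acquisition", "pupil")] = stats.rm_anova(
            acq_pupil, "response_mm", ["orientation_deg", "half"]
        )
        anovas[("acquisition", "ratings")] = stats.rm_anova(
            rating_tables["acquisition"], "rating", ["orientation_deg"]
        )
        ttests["acquisition:ratings:cs+_vs_cs-45"] = _posthoc(
            rating_tables["acquisition"], "rating", None, None, config.alpha
        )

    bf_map, bf_pool = None, {}
    if "context" in config.phases:
        sensor_snr = snr_table[
            (snr_table["phase"] == "context")
            & ~snr_table["pooled"]
            & snr_table["orientation_deg"].isin(bayes.WEIGHT_LEVELS)
        ]
        if config.bayes_sensors == "pool":
            sensor_snr = sensor_snr[
                sensor_snr["sensor"].isin(net.occipital_pool)
            ]
        logger.info("Bayes topography over %d sensors",
                    sensor_snr["sensor"].nunique())
        bf_map = bayes.bf_topography(
            sensor_snr, frequencies=config.frequencies,
            nodes=config.bayes_nodes,
        )
        pooled_b = snr_table[
            (snr_table["phase"] == "context")
            & snr_table["pooled"]
            & snr_table["orientation_deg"].isin(bayes.WEIGHT_LEVELS)
        ]
        for f in config.frequencies:
            sub = pooled_b[pooled_b["frequency_hz"] == f]
            for name, model, with_ctx in (
                ("sharpening", bayes.SHARPENING, True),
                ("generalization", bayes.GENERALIZATION, True),
                ("context", None, True),
            ):
                design = bayes.build_design(sub, model, include_context=with_ctx)
                bf_pool[f"{name}@{f:g}hz"] = bayes.jzs_bf(
                    design, nodes=config.bayes_nodes
                )

    power_result = simulate_power(config.power)

    summary = {
        "n_subjects": config.n_subjects,
        "excluded_subjects_acquisition": excluded_acq,
        "mean_retained_fraction": float(retention["retained"].mean()),
        "power_proportion": power_result.proportion,
        "power_analytic": analytic_power(config.power),
    }
    if "context" in config.phases:
        for f in config.frequencies:
            key = f"snr_{f:g}hz"
            res = anovas[("context", key)]
            summary[f"context_effect_{f:g}hz_significant"] = bool(
                res["context"].p < config.alpha
            )
            summary[f"cue_effect_{f:g}hz_significant"] = bool(
                res["orientation_deg"].p < config.alpha
            )
        for k, v in bf_pool.items():
            summary[f"log_bf_pool:{k}"] = v

    return RunReport(
        config=config,
        snr_table=snr_table,
        pupil_table=pupil_table,
        rating_tables=rating_tables,
        anovas=anovas,
        ttests=ttests,
        bf_map=bf_map,
        bf_pool=bf_pool,
        power=power_result,
        retention=retention,
        excluded_subjects_acquisition=tuple(excluded_acq),
        summary=summary,
    )
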