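"""End-to-end orchestration: simulate -> clean -> spectra -> coherence ->
behavior -> correlate, as one reproducible run.

A run is a pure function of its :class:`RunConfig`: identical config
(including the master seed) yields byte-identical exported CSVs, which
the manifest records with content checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import ResponseParams, simulate_session
from .errors import ResteegError
from .io import write_fixture
from .preprocess import PreprocessConfig, preprocess_recording
from .recording import Recording
from .spectral import SpectralConfig, band_coherence_network, band_power_table
from .statsmap import (
    MEASURES,
    correlation_map,
    ec_eo_alpha_contrast,
    edge_correlation_network,
    significant_edges_by_band,
)
from .synth import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run depends on."""

    output_dir: str = "resteeg-run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    alpha: float = 0.05
    multiplicity: str = "none"
    power: str = "relative"
    behavior_source: str = "covariates"  # or "simulated"
    save_fixtures: bool = False

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            return obj

        return convert(self)


def validate_config(config: RunConfig) -> list[str]:
    """Cross-field consistency checks; returns human-readable problems.

    Field-level invariants are enforced by the dataclasses themselves;
    this catches what no single object can see (Nyquist vs band edges,
    duration vs minimum, segmentation vs duration).
    """
    problems: list[str] = []
    fs = config.cohort.sample_rate
    nyquist = fs / 2.0
    scheme = config.cohort.band_scheme
    for band in scheme.names:
        low, high = scheme.edges(band)
        if high > nyquist:
            problems.append(
                f"band {band} upper edge {high} Hz exceeds Nyquist {nyquist} Hz"
            )
    if config.spectral.span[1] > nyquist:
        problems.append(
            f"spectral span {config.spectral.span} exceeds Nyquist {nyquist} Hz"
        )
    if config.preprocess.bandpass_high_hz >= nyquist:
        problems.append(
            f"band-pass high edge {config.preprocess.bandpass_high_hz} Hz "
            f"must be below Nyquist {nyquist} Hz"
        )
    # (a too-short cohort duration vs the minimum retained duration is
    # left to the runtime guard, which names the failing subject)
    if config.cohort.duration_s < 2 * config.spectral.epoch_s:
        problems.append("recordings too short for at least 2 Welch segments")
    if not 0 < config.alpha <= 1:
        problems.append(f"alpha {config.alpha} outside (0, 1]")
    if config.multiplicity not in ("none", "bh"):
        problems.append(f"unknown multiplicity method {config.multiplicity!r}")
    if config.behavior_source not in ("covariates", "simulated"):
        problems.append(f"unknown behavior source {config.behavior_source!r}")
    return problems


@dataclass
class ReportBundle:
    """All exported tables of one run plus the manifest describing them."""

    output_dir: Path
    tables: dict[str, pd.DataFrame]
    manifest: dict

    def path(self, name: str) -> Path:
        return Path(self.manifest["files"][name]["path"])


def _export(tables: dict[str, pd.DataFrame], out_dir: Path) -> dict:
    files = {}
    for name, frame in tables.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        files[name] = {"path": str(path), "rows": int(len(frame)), "sha256": digest}
        logger.info("stage output %s: %d rows", name, len(frame))
    return files


def _simulated_behavior(cohort_behavior: pd.DataFrame, master_seed: int) -> pd.DataFrame:
    """Per-trial task simulation wired to the cohort covariates."""
    rows = []
    for i, row in cohort_behavior.iterrows():
        params = ResponseParams(
            p_correct_target=min(row["accuracy_pct"] / 100.0, 1.0),
            p_correct_nontarget=min(row["accuracy_pct"] / 100.0, 1.0),
            rt_mean_ms=row["mean_rt_ms"],
        )
        summary = simulate_session(
            params,
            seed=np.random.SeedSequence(entropy=master_seed, spawn_key=(4, int(i))),
            subject_id=row["subject"],
        )
        d = summary.as_dict()
        d["subject"] = d.pop("subject_id")
        rows.append(d)
    frame = pd.DataFrame(rows)
    frame["mean_rt_ms"] = frame["mean_rt_ms"].astype(float)
    frame["accuracy_pct"] = frame["accuracy_pct"].astype(float)
    return frame


def preprocess_cohort(
    recordings: list[Recording], config: PreprocessConfig
) -> tuple[list[Recording], pd.DataFrame]:
    """Clean every recording; returns cleaned list + cleaning report table."""
    cleaned, reports = [], []
    for rec in recordings:
        out, report = preprocess_recording(rec, config)
        cleaned.append(out)
        reports.append(
            {
                "subject": report.subject_id,
                "condition": report.condition,
                "channels_removed": ";".join(
                    f"{name}:{reason}" for name, reason in report.channels_removed
                ),
                "windows_reconstructed": report.windows_reconstructed,
                "seconds_reconstructed": report.seconds_reconstructed,
                "retained_duration_s": report.retained_duration_s,
            }
        )
    return cleaned, pd.DataFrame(reports)


def run_pipeline(config: RunConfig | None = None) -> ReportBundle:
    """Execute every stage in order and export the report bundle.

    Any stage failure aborts the run; a FAILED manifest naming the stage
    is written next to whatever partial outputs exist.
    """
    config = config or RunConfig()
    problems = validate_config(config)
    if problems:
        raise ResteegError("invalid configuration: " + "; ".join(problems))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    json_exports: dict[str, dict] = {}
    stage = "simulate"
    try:
        recordings, covariates, truth = generate_cohort(config.cohort)
        logger.info("simulate: %d recordings, %d subjects",
                    len(recordings), config.cohort.n_subjects)
        if config.save_fixtures:
            fix_dir = out_dir / "fixtures"
            for rec in recordings:
                write_fixture(rec, fix_dir / f"{rec.subject_id}_{rec.condition}")
        tables["behavior_covariates"] = covariates

        stage = "preprocess"
        cleaned, cleaning = preprocess_cohort(recordings, config.preprocess)
        tables["cleaning_report"] = cleaning

        stage = "spectra"
        tables["band_power"] = band_power_table(
            cleaned, config.cohort.band_scheme, config.spectral, relative=True
        )

        stage = "coherence"
        tables["coherence_edges"] = pd.concat(
            [
                band_coherence_network(
                    rec, config.cohort.band_scheme, config.spectral
                ).edge_list()
                for rec in cleaned
            ],
            ignore_index=True,
        )

        stage = "behavior"
        if config.behavior_source == "simulated":
            behavior = _simulated_behavior(covariates, config.cohort.master_seed)
        else:
            behavior = covariates
        tables["behavior_summary"] = behavior

        stage = "correlate"
        for measure in MEASURES:
            tables[f"correlation_map_{measure}"] = correlation_map(
                tables["band_power"], behavior, measure,
                power=config.power, alpha=config.alpha,
                multiplicity=config.multiplicity,
            )
            net = edge_correlation_network(
                tables["coherence_edges"], behavior, measure,
                alpha=config.alpha, multiplicity=config.multiplicity,
            )
            tables[f"edge_correlation_{measure}"] = net
            json_exports[f"significant_edges_{measure}"] = (
                significant_edges_by_band(net)
            )
        if {"eyes_open", "eyes_closed"} <= set(config.cohort.conditions):
            contrast = ec_eo_alpha_contrast(tables["band_power"])
            tables["contrast_summary"] = pd.DataFrame([contrast])
    except Exception as exc:
        files = _export(tables, out_dir)
        failed = {
            "status": "FAILED",
            "stage": stage,
            "error": str(exc),
            "config": config.to_dict(),
            "files": files,
        }
        (out_dir / "manifest.json").write_text(json.dumps(failed, indent=1))
        raise

    files = _export(tables, out_dir)
    for name, payload in json_exports.items():
        path = out_dir / f"{name}.json"
        path.write_text(json.dumps(payload, indent=1))
        files[name] = {
            "path": str(path),
            "rows": sum(len(v) for v in payload.values()),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
    config_dict = config.to_dict()
    manifest = {
        "status": "OK",
        "package": "resteeg",
        "version": __version__,
        "master_seed": config.cohort.master_seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return ReportBundle(output_dir=out_dir, tables=tables, manifest=manifest)
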