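"""Cohort-level replication protocols.

Each function runs the full pipeline path relevant to one published
cohort statistic on synthetic cohorts configured to the reference study
conditions, and returns the recovered quantity: planted power-behavior
correlation recovery, eyes-closed occipital-alpha level recovery,
behavioral round trips, and null calibration of the correlation map.

These are the package's own reference experiments; the acceptance
script and the heavier tests both call them, so the measured numbers
always come from the same code path users run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import ResponseParams, simulate_session
from .montage import OCCIPITAL
from .pipeline import preprocess_cohort
from .preprocess import PreprocessConfig
from .spectral import SpectralConfig, band_power_table
from .statsmap import correlation_map
from .synth import CohortConfig, PlantedEffect, generate_cohort


def _replicate_seed(seed: int, *key: int) -> int:
    """Deterministic sub-seed for one replicate (< 2**32)."""
    return int(np.random.SeedSequence(entropy=seed, spawn_key=key).generate_state(1)[0])


def _eyes_closed_map(
    config: CohortConfig, measure: str, power: str = "absolute"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate -> preprocess -> band power -> correlation map, eyes closed."""
    recordings, behavior, _ = generate_cohort(config)
    pre = PreprocessConfig(min_duration_s=min(60.0, config.duration_s))
    cleaned, _ = preprocess_cohort(recordings, pre)
    table = band_power_table(cleaned, config.band_scheme, SpectralConfig(),
                             relative=(power == "relative"))
    return correlation_map(table, behavior, measure, power=power), behavior


def recover_planted_correlation(
    channel: str,
    band: str,
    measure: str,
    rho: float,
    n_cohorts: int = 200,
    seed: int = 0,
    n_subjects: int = 43,
    duration_s: float = 60.0,
) -> dict:
    """Mean recovered Pearson r for one planted power-behavior effect.

    For each replicate cohort: plant the single effect, generate the
    eyes-closed recordings, run the cleaning chain, compute absolute
    band power, correlate against the behavioral measure, and read the
    planted cell off the map.  Absolute (density-scale) power is the
    matched feature for the planted effect; see the methods note.
    """
    effect = PlantedEffect((channel, band), measure, rho)
    values = np.empty(n_cohorts)
    for k in range(n_cohorts):
        config = CohortConfig(
            n_subjects=n_subjects,
            duration_s=duration_s,
            planted_effects=(effect,),
            conditions=("eyes_closed",),
            master_seed=_replicate_seed(seed, 1, k),
        )
        cmap, _ = _eyes_closed_map(config, measure)
        cell = cmap[(cmap["band"] == band) & (cmap["channel"] == channel)]
        values[k] = float(cell["rho"].iloc[0])
    return {
        "mean_r": float(values.mean()),
        "sd_r": float(values.std(ddof=1)),
        "planted_rho": rho,
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }


def recover_ec_occipital_alpha(
    seed: int = 0,
    n_cohorts: int = 1,
    n_subjects: int = 43,
    duration_s: float = 60.0,
) -> dict:
    """Group mean eyes-closed occipital alpha density through the pipeline.

    The default generator targets the published eyes-closed level; each
    replicate cohort is generated, cleaned, and Welch band powers
    computed; the group mean alpha absolute density over O1/O2 is
    averaged across replicates.
    """
    means = []
    for k in range(n_cohorts):
        config = CohortConfig(
            n_subjects=n_subjects,
            duration_s=duration_s,
            conditions=("eyes_closed",),
            master_seed=_replicate_seed(seed, 2, k),
        )
        recordings, _, _ = generate_cohort(config)
        cleaned, _ = preprocess_cohort(
            recordings, PreprocessConfig(min_duration_s=min(60.0, duration_s))
        )
        table = band_power_table(cleaned, relative=False)
        occ = table[
            (table["band"] == "alpha") & (table["channel"].isin(OCCIPITAL))
        ]
        means.append(float(occ.groupby("subject")["absolute_density"].mean().mean()))
    return {
        "mean_density": float(np.mean(means)),
        "per_cohort": means,
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }


def behavioral_round_trip(
    params: ResponseParams | None = None,
    n_replicates: int = 200,
    n_subjects: int = 43,
    seed: int = 0,
) -> dict:
    """Cohort mean task statistics from full simulated sessions.

    Simulates ``n_replicates`` cohorts of ``n_subjects`` full sessions
    (16 trials x 12 items), scores every log, and averages the per-
    subject summaries.
    """
    params = params or ResponseParams()
    acc_t, acc_nt, rt_t, rt_nt = [], [], [], []
    for k in range(n_replicates):
        for i in range(n_subjects):
            summary = simulate_session(
                params,
                seed=np.random.SeedSequence(entropy=seed, spawn_key=(3, k, i)),
            )
            acc_t.append(summary.accuracy_target_pct)
            acc_nt.append(summary.accuracy_nontarget_pct)
            if summary.mean_rt_correct_target_ms is not None:
                rt_t.append(summary.mean_rt_correct_target_ms)
            if summary.mean_rt_correct_nontarget_ms is not None:
                rt_nt.append(summary.mean_rt_correct_nontarget_ms)
    return {
        "accuracy_target_pct": float(np.mean(acc_t)),
        "accuracy_nontarget_pct": float(np.mean(acc_nt)),
        "rt_correct_target_ms": float(np.mean(rt_t)),
        "rt_correct_nontarget_ms": float(np.mean(rt_nt)),
        "n_sessions": n_replicates * n_subjects,
    }


def null_map_calibration(
    n_cohorts: int = 30,
    seed: int = 0,
    n_subjects: int = 43,
    duration_s: float = 30.0,
    alpha: float = 0.05,
    measure: str = "mean_rt_ms",
) -> dict:
    """False-positive rate of the uncorrected correlation map under the null.

    Effect-free cohorts: the behavioral covariate is pure noise, so
    every one of the 70 map cells is a null test; the fraction with
    ``p < alpha`` should sit at ``alpha`` up to binomial noise.
    """
    hits = 0
    total = 0
    for k in range(n_cohorts):
        config = CohortConfig(
            n_subjects=n_subjects,
            duration_s=duration_s,
            conditions=("eyes_closed",),
            master_seed=_replicate_seed(seed, 4, k),
        )
        cmap, _ = _eyes_closed_map(config, measure)
        hits += int((cmap["p"] < alpha).sum())
        total += len(cmap)
    return {
        "fraction_significant": hits / total,
        "n_tests": total,
        "alpha": alpha,
    }
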