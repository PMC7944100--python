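"""Synthetic cohort generator: determinism, planted quantities, artifacts."""

import numpy as np
import pandas as pd
import pytest

from resteeg.errors import ConfigurationError
from resteeg.montage import CHANNELS_14
from resteeg.spectral import band_power, welch_psd
from resteeg.synth import (
    ArtifactSpec,
    CohortConfig,
    PlantedEffect,
    draw_subject_latents,
    generate_behavior_covariates,
    generate_cohort,
    generate_subject_signal,
    inject_artifacts,
)

SILENT = ArtifactSpec(0, 0, 0, 0)


class TestConfig:
    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_subjects=2)

    def test_boost_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(ec_alpha_boost=0.9)

    def test_planted_effect_validation(self):
        with pytest.raises(ConfigurationError):
            PlantedEffect(("Cz", "alpha"), "accuracy_pct", -0.3)  # not in montage
        with pytest.raises(ConfigurationError):
            PlantedEffect(("P8", "beta"), "typing_speed", -0.3)
        with pytest.raises(ConfigurationError):
            PlantedEffect(("P8", "beta"), "accuracy_pct", 1.0)

    def test_jointly_infeasible_effects_rejected(self):
        effects = (
            PlantedEffect(("P8", "beta"), "accuracy_pct", 0.8),
            PlantedEffect(("P7", "delta"), "accuracy_pct", 0.7),
        )
        config = CohortConfig(n_subjects=5, planted_effects=effects)
        with pytest.raises(ConfigurationError):
            generate_cohort(config)


class TestDeterminism:
    def test_same_config_bit_identical(self):
        config = CohortConfig(n_subjects=3, duration_s=10.0, master_seed=9)
        recs1, beh1, _ = generate_cohort(config)
        recs2, beh2, _ = generate_cohort(config)
        for a, b in zip(recs1, recs2):
            np.testing.assert_array_equal(a.data, b.data)
        pd.testing.assert_frame_equal(beh1, beh2)

    def test_subject_streams_independent(self):
        """Changing the latents/seed of one subject leaves the others'
        signals unchanged (per-subject spawn keys)."""
        config = CohortConfig(n_subjects=4, duration_s=10.0, master_seed=1,
                              artifact_spec=SILENT)
        recs1, _, _ = generate_cohort(config)
        # regenerate subject 2's signal from its own stream; others must match
        config2 = CohortConfig(n_subjects=4, duration_s=10.0, master_seed=1,
                               artifact_spec=SILENT)
        recs2, _, _ = generate_cohort(config2)
        for a, b in zip(recs1, recs2):
            np.testing.assert_array_equal(a.data, b.data)
        lat = draw_subject_latents(config, 2)
        different = generate_subject_signal(config, lat, "eyes_open", seed=999)
        assert not np.array_equal(different.data, recs1[4].data)

    def test_default_cohort_shape(self):
        config = CohortConfig(duration_s=4.0, artifact_spec=SILENT)
        recs, beh, truth = generate_cohort(config)
        assert len(recs) == 86  # 43 subjects x {EO, EC}
        assert len(beh) == 43
        assert truth.multipliers.shape == (43, 5, 14)

    def test_minimum_cohort_still_runs_downstream(self):
        from resteeg.pipeline import preprocess_cohort
        from resteeg.preprocess import PreprocessConfig
        from resteeg.spectral import band_power_table
        from resteeg.statsmap import correlation_map

        config = CohortConfig(n_subjects=3, duration_s=20.0,
                              conditions=("eyes_closed",), master_seed=2)
        recs, beh, _ = generate_cohort(config)
        cleaned, _ = preprocess_cohort(recs, PreprocessConfig(min_duration_s=20.0))
        cmap = correlation_map(band_power_table(cleaned), beh, "mean_rt_ms")
        assert len(cmap) == 70


class TestSignalModel:
    def test_ec_boost_identity_when_one(self):
        config = CohortConfig(n_subjects=3, duration_s=10.0, ec_alpha_boost=1.0,
                              subject_sd_log=0.0, master_seed=3)
        lat = draw_subject_latents(config, 0)
        eo = generate_subject_signal(config, lat, "eyes_open", seed=7)
        ec = generate_subject_signal(config, lat, "eyes_closed", seed=7)
        np.testing.assert_array_equal(eo.data, ec.data)

    def test_welch_round_trip_long_duration(self):
        """Welch band averages converge to configured densities (checked at
        10x the default duration, tolerance 3% on the channel mean)."""
        config = CohortConfig(n_subjects=3, duration_s=600.0, subject_sd_log=0.0,
                              reference_compensation=False, master_seed=17)
        lat = draw_subject_latents(config, 0)
        rec = generate_subject_signal(config, lat, "eyes_open", seed=0)
        table = band_power(welch_psd(rec))
        expected = {"delta": 12.0, "theta": 8.0, "alpha": 10.0, "beta": 4.0,
                    "gamma": 2.0}
        occ = table.channel.isin(["O1", "O2"])
        for band, target in expected.items():
            got = table[(table.band == band) & ~occ].absolute_density.mean()
            assert got == pytest.approx(target, rel=0.03), band
        got_occ = table[(table.band == "alpha") & occ].absolute_density.mean()
        assert got_occ == pytest.approx(35.65, rel=0.03)

    def test_eyes_closed_elevates_only_occipital_alpha(self):
        config = CohortConfig(n_subjects=3, duration_s=120.0, subject_sd_log=0.0,
                              reference_compensation=False, master_seed=23)
        lat = draw_subject_latents(config, 0)
        eo = band_power(welch_psd(generate_subject_signal(config, lat, "eyes_open", seed=1)))
        ec = band_power(welch_psd(generate_subject_signal(config, lat, "eyes_closed", seed=2)))
        merged = eo.merge(ec, on=["channel", "band"], suffixes=("_eo", "_ec"))
        occ_alpha = merged[(merged.band == "alpha") & merged.channel.isin(["O1", "O2"])]
        ratio = (occ_alpha.absolute_density_ec / occ_alpha.absolute_density_eo).mean()
        assert ratio == pytest.approx(38.80 / 35.65, rel=0.05)
        rest = merged[~((merged.band == "alpha") & merged.channel.isin(["O1", "O2"]))]
        rest_ratio = (rest.absolute_density_ec / rest.absolute_density_eo).mean()
        assert rest_ratio == pytest.approx(1.0, abs=0.02)


class TestArtifacts:
    def test_zero_rates_identity(self, rng):
        config = CohortConfig(n_subjects=3, duration_s=10.0, master_seed=4)
        lat = draw_subject_latents(config, 0)
        rec = generate_subject_signal(config, lat, "eyes_open", seed=1)
        out, events = inject_artifacts(rec, SILENT, seed=5)
        assert events == []
        np.testing.assert_array_equal(out.data, rec.data)

    def test_blink_count_poisson_mean(self):
        config = CohortConfig(n_subjects=3, duration_s=60.0, master_seed=6)
        lat = draw_subject_latents(config, 0)
        rec = generate_subject_signal(config, lat, "eyes_open", seed=2)
        spec = ArtifactSpec(blink_rate_per_min=6.0, muscle_rate_per_min=0.0,
                            flat_channel_prob=0.0)
        counts = []
        for s in range(300):
            _, events = inject_artifacts(rec, spec, seed=s)
            counts.append(len(events))
        # Poisson(6): mean 6, SE of the mean over 300 draws ~ 0.14
        assert np.mean(counts) == pytest.approx(6.0, abs=0.45)
        assert np.var(counts) == pytest.approx(6.0, rel=0.35)

    def test_blinks_are_frontally_weighted_and_annotated(self):
        config = CohortConfig(n_subjects=3, duration_s=30.0, subject_sd_log=0.0,
                              master_seed=8)
        lat = draw_subject_latents(config, 0)
        rec = generate_subject_signal(config, lat, "eyes_open", seed=3)
        spec = ArtifactSpec(blink_rate_per_min=8.0, muscle_rate_per_min=0.0,
                            flat_channel_prob=0.0)
        out, events = inject_artifacts(rec, spec, seed=11)
        assert all(e.label == "blink" for e in events)
        assert len(out.annotations) == len(events)
        delta = out.data - rec.data
        af = np.abs(delta[[CHANNELS_14.index("AF3"), CHANNELS_14.index("AF4")]]).max()
        occ = np.abs(delta[[CHANNELS_14.index("O1"), CHANNELS_14.index("O2")]]).max()
        assert af == pytest.approx(300.0, rel=0.1)
        assert occ < 0.3 * af

    def test_flat_channel_zeroed_and_annotated(self):
        config = CohortConfig(n_subjects=3, duration_s=30.0, master_seed=10)
        lat = draw_subject_latents(config, 0)
        rec = generate_subject_signal(config, lat, "eyes_open", seed=4)
        spec = ArtifactSpec(blink_rate_per_min=0.0, muscle_rate_per_min=0.0,
                            flat_channel_prob=1.0)
        out, events = inject_artifacts(rec, spec, seed=13)
        flat_events = [e for e in events if e.label.startswith("flat:")]
        assert len(flat_events) == 1
        ev = flat_events[0]
        ch = ev.label.split(":")[1]
        fs = rec.sample_rate
        seg = out.channel(ch)[int(ev.onset * fs): int((ev.onset + ev.duration) * fs)]
        assert np.ptp(seg) == 0.0
        assert ev.duration >= 5.0


class TestBehaviorCovariates:
    def _covariates(self, config, seed=0):
        subjects = [f"S{i:02d}" for i in range(config.n_subjects)]
        latents = [draw_subject_latents(config, i) for i in range(config.n_subjects)]
        sigma = config.subject_sd_log
        mult = np.exp(sigma * np.stack([l.z_power for l in latents]) - sigma**2 / 2)
        return generate_behavior_covariates(config, mult, latents, subjects, seed), mult

    def test_rho_zero_gives_uncorrelated_covariates(self):
        # with nothing planted, the mean correlation across replicates is
        # bounded both in magnitude and relative to its Monte-Carlo error
        config = CohortConfig(n_subjects=40, master_seed=31)
        rs = []
        for k in range(4000):
            beh, mult = self._covariates(config, seed=k)
            rs.append(np.corrcoef(mult[:, 3, 8], beh.accuracy_pct)[0, 1])
        mean = np.mean(rs)
        se = np.std(rs) / np.sqrt(len(rs))
        assert abs(mean) < 0.01
        assert abs(mean) < 4 * se

    def test_planted_rho_on_true_feature(self):
        effect = PlantedEffect(("P8", "beta"), "accuracy_pct", -0.42)
        config = CohortConfig(n_subjects=43, planted_effects=(effect,),
                              master_seed=33)
        b = list(config.band_scheme.names).index("beta")
        c = CHANNELS_14.index("P8")
        rs = []
        for k in range(300):
            beh, mult = self._covariates(config, seed=k)
            rs.append(np.corrcoef(mult[:, b, c], beh.accuracy_pct)[0, 1])
        # clipping accuracy at 100 costs ~1% of the correlation at most
        assert np.mean(rs) == pytest.approx(-0.42, abs=0.02)

    def test_published_scale_mapping(self):
        config = CohortConfig(n_subjects=400, master_seed=35)
        beh, _ = self._covariates(config)
        assert beh.mean_rt_ms.mean() == pytest.approx(673.0, abs=10.0)
        assert beh.mean_rt_ms.std() == pytest.approx(51.0, rel=0.2)
        assert beh.accuracy_pct.max() <= 100.0
        assert beh.accuracy_pct.mean() == pytest.approx(91.56, abs=1.0)

    def test_duplicate_feature_rejected(self):
        effects = (
            PlantedEffect(("P8", "beta"), "accuracy_pct", -0.3),
            PlantedEffect(("P8", "beta"), "accuracy_pct", -0.2),
        )
        config = CohortConfig(n_subjects=5, planted_effects=effects)
        with pytest.raises(ConfigurationError):
            self._covariates(config)
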