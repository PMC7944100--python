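"""Electrode-wise correlation mapping with a planted effect.

Generates an eyes-closed cohort with delta power at P7 correlated to
mean reaction time, runs the cleaning chain and band power, and shows
the planted cell surfacing in the 70-cell correlation map.
"""

from resteeg import CohortConfig, PlantedEffect, correlation_map, generate_cohort
from resteeg.pipeline import preprocess_cohort
from resteeg.preprocess import PreprocessConfig
from resteeg.spectral import band_power_table

config = CohortConfig(
    n_subjects=43,
    duration_s=30.0,
    planted_effects=(PlantedEffect(("P7", "delta"), "mean_rt_ms", -0.31),),
    conditions=("eyes_closed",),
    master_seed=12,
)
recordings, behavior, _ = generate_cohort(config)
cleaned, report = preprocess_cohort(recordings, PreprocessConfig(min_duration_s=30.0))
table = band_power_table(cleaned, relative=False)

cmap = correlation_map(table, behavior, "mean_rt_ms", power="absolute")
print(f"{len(cmap)} (band, channel) cells; "
      f"{int(cmap.significant.sum())} significant at p < 0.05 uncorrected")
top = cmap.reindex(cmap.rho.abs().sort_values(ascending=False).index).head(3)
print(top[["band", "channel", "rho", "p"]].round(4).to_string(index=False))
print("(the planted delta/P7 cell should top the list; at n = 43 a single "
      "cohort's r scatters ~0.13 around the planted -0.31)")
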