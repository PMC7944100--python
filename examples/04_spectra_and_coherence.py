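"""Band power and coherence on synthetic eyes-closed vs eyes-open data.

Shows the 0.25 Hz Welch grid, the eyes-closed occipital alpha
elevation, and a planted coherent edge standing out of the network.
"""

import numpy as np

from resteeg import band_coherence_network, band_power, welch_psd
from resteeg.synth import CohortConfig, draw_subject_latents, generate_subject_signal

config = CohortConfig(
    n_subjects=3,
    duration_s=60.0,
    subject_sd_log=0.0,  # no subject variability: cleaner demonstration
    reference_compensation=False,  # measuring the raw signal here, not the
    fixed_coherence_edges=(("F3", "P7", "alpha", 0.8),),  # re-referenced one
    master_seed=5,
)
latents = draw_subject_latents(config, 0)

for condition in ("eyes_open", "eyes_closed"):
    rec = generate_subject_signal(config, latents, condition, seed=9)
    psd = welch_psd(rec)
    table = band_power(psd)
    occ = table[(table.band == "alpha") & table.channel.isin(["O1", "O2"])]
    print(f"{condition}: grid spacing {psd.frequencies[1] - psd.frequencies[0]:.2f} Hz, "
          f"{psd.n_segments} segments; occipital alpha "
          f"{occ.absolute_density.mean():.1f} uV^2/Hz")
# eyes-closed should sit ~8.8% above eyes-open (38.80 vs 35.65 targets)

rec = generate_subject_signal(config, latents, "eyes_closed", seed=9)
net = band_coherence_network(rec)
edges = net.edge_list()
alpha = edges[edges.band == "alpha"].sort_values("coherence", ascending=False)
print("\nstrongest alpha-band coherence edges:")
print(alpha.head(3)[["ch_i", "ch_j", "coherence"]].round(3).to_string(index=False))
print("(the F3-P7 edge was planted at 0.8; the rest sit near the "
      f"estimator bias ~1/29 = {1 / 29:.3f})")
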