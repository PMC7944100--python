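"""One reproducible end-to-end run: simulate -> clean -> spectra ->
coherence -> behavior -> correlate, with a checksummed report bundle.

The same run is available from the shell as
`resteeg run-all --config cfg.yaml --out out/`.
"""

import tempfile

from resteeg import RunConfig, run_pipeline
from resteeg.synth import CohortConfig

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(
        output_dir=tmp,
        cohort=CohortConfig(n_subjects=8, duration_s=60.0, master_seed=42),
    )
    bundle = run_pipeline(config)

    print("exported tables:")
    for name, info in bundle.manifest["files"].items():
        print(f"  {name:32s} {info['rows']:5d} rows  sha256 {info['sha256'][:10]}…")

    contrast = bundle.tables["contrast_summary"].iloc[0]
    print(f"\nEC/EO occipital alpha: {contrast.ec_mean:.1f} vs "
          f"{contrast.eo_mean:.1f} uV^2/Hz (KW p = {contrast.kw_p:.3g})")
    print("Identical config + seed reproduce these checksums byte-for-byte;")
    print("at n = 8 the EC > EO contrast is usually visible but not always "
          "significant.")
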