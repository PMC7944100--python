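"""Montage geometry and recording I/O.

Builds the 14-channel wearable-headset montage, writes a short
recording in the internal fixture format, and reads it back bit-exact.
"""

import tempfile
from pathlib import Path

import numpy as np

from resteeg import builtin_montage, read_recording, write_fixture
from resteeg.recording import Annotation, Recording

montage = builtin_montage()
print(f"{montage.n_channels} channels:", ", ".join(montage.channel_names))
print(f"P7 sits at {montage.position('P7').round(3)} (head radius 1, nose +y);")
print(f"P7-P8 head-plane distance: {montage.distance('P7', 'P8'):.3f}")

rng = np.random.default_rng(0)
rec = Recording(
    subject_id="demo",
    condition="eyes_closed",
    sample_rate=128.0,
    data=rng.standard_normal((14, 5 * 128)),  # 5 s of noise, uV
    montage=montage,
    annotations=[Annotation(1.25, 0.4, "blink")],
)

with tempfile.TemporaryDirectory() as tmp:
    path = write_fixture(rec, Path(tmp) / "demo_ec")
    back = read_recording(path)
    identical = np.array_equal(back.data, rec.data)
    print(f"fixture round trip bit-exact: {identical}; "
          f"annotations preserved: {[a.label for a in back.annotations]}")
# The True above is the format's contract: regression fixtures only make
# sense if what you read is exactly what you wrote.
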