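"""Generate labeled synthetic ECG records and write them to disk.

Builds a clean 2-minute normal record and an ST-elevated ischemic record
with realistic noise (baseline wander, 50 Hz mains, muscle noise), then
round-trips one through the CSV + sidecar format.
"""

import numpy as np

from cwdetect import NoiseParams, generate_record, read_record, write_record

normal = generate_record("normal", minutes=2, n_leads=2, fs=250.0, seed=1)
ischemic = generate_record(
    "ischemia_st_elev", minutes=2, n_leads=2, fs=250.0, seed=2, noise=NoiseParams()
)

for rec in (normal, ischemic):
    print(
        f"{rec.record_id}: {rec.n_leads} leads x {rec.n_samples} samples "
        f"({rec.duration / 60:.0f} min at {rec.fs:g} Hz), label={rec.label}, "
        f"peak amplitude {rec.signals.max():.2f} mV"
    )

write_record(ischemic, "scratch_example_record.csv")
back = read_record("scratch_example_record.csv")
print(
    "CSV round trip: max abs difference "
    f"{np.abs(back.signals - ischemic.signals).max():.2e} mV "
    "(lossless to the declared precision)"
)
# The ischemic record differs from a normal one only by a +0.15 mV plateau on
# each beat's ST segment plus the noise mixture - exactly the morphology the
# detection pipeline is built to pick up.
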