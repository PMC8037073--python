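"""ST/PR band-power features of normal vs ischemic synthetic minutes.

Runs the full conditioning chain (resample, 0.5 Hz high-pass, 2-35 Hz
band-pass, z-score), segments into 1-minute slots, and extracts the
normalized 11-14 Hz (ST) and 5-8.5 Hz (PR) band-power percentages from the
positive-part Choi-Williams matrix of every minute.
"""

from cwdetect import NoiseParams, generate_record
from cwdetect.config import PipelineConfig
from cwdetect.pipeline import compute_features

records = [
    generate_record("normal", minutes=3, n_leads=1, seed=5, noise=NoiseParams(),
                    record_id="normal-demo"),
    generate_record("ischemia_st_elev", minutes=3, n_leads=1, seed=6,
                    noise=NoiseParams(), record_id="ischemia-demo"),
]

table = compute_features(records, PipelineConfig())
print(table.data.to_string(index=False))

means = table.data.groupby("label")[["p_st", "p_pr"]].mean()
print("\nper-class means:")
print(means.to_string())
print(
    "\nThe ST-segment level shift of the ischemic record raises its 11-14 Hz "
    "band share (p_st); the (p_st, p_pr) pair per minute is what the SVM "
    "classifies."
)
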