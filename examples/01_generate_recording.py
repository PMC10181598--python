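"""Generate a synthetic two-channel EOG session and describe it.

The default protocol is five 10-second movement periods (down, up, blink,
left, right) sampled at 650 Hz: 32,500 samples per channel, band-limited to
0.5-50 Hz, quantized to 11 bits inside a -0.3 ... 0.5 V envelope.
"""

import numpy as np

import eogwave as ew

recording = ew.generate_recording(ew.SyntheticConfig(seed=4))

print(f"samples per channel : {recording.n_samples}")
print(f"duration            : {recording.duration:.1f} s")
print(f"sampling rate       : {recording.sampling_rate:.0f} Hz")
for class_id, name in enumerate(ew.CLASS_NAMES):
    mask = recording.labels == class_id
    v = recording.vertical[mask]
    h = recording.horizontal[mask]
    print(
        f"  class {class_id} ({name:5s}): {mask.sum()} samples, "
        f"H range [{h.min():+.3f}, {h.max():+.3f}] V, "
        f"V range [{v.min():+.3f}, {v.max():+.3f}] V"
    )

# The signed ranges show each movement's action-potential polarity: right/up
# deflect their channel positive, left/down negative, and blink spikes
# dominate the vertical channel.

ew.write_recording(recording, "session.csv", overwrite=True)
print("wrote session.csv (columns h_volts, v_volts, label)")
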