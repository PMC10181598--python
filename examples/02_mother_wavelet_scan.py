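"""Score candidate mother wavelets by Shannon entropy of their detail levels.

Each channel is decomposed to five levels per candidate; each level's detail
coefficients are scored by the entropy of their normalized energy
distribution (in bits). Lower total entropy = less information disorder =
a wavelet whose shape matches the signal better.
"""

import eogwave as ew

recording = ew.generate_recording(ew.SyntheticConfig(seed=4))
scan = ew.scan_families(recording)  # haar, coif3, sym3, fk4, meyr, bior3.1, rbio3.1

print("Horizontal channel entropy (bits) per level:")
print(scan.horizontal.to_frame().round(3).to_string())
print()
print("Vertical channel entropy (bits) per level:")
print(scan.vertical.to_frame().round(3).to_string())

mother = ew.select_mother(scan)  # minimizes entropy summed over levels+channels
print(f"\nselected mother wavelet: {mother.name}")
print(
    "The level-4 detail series of this wavelet is the smoothed signal the "
    "feature stage consumes."
)
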