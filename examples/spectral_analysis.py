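"""Band powers and decibel baseline normalization on known signals.

A pure 10 Hz tone must land almost entirely in the alpha band, and a known
power ratio between task and baseline must read as its textbook decibel
value: 10*log10(ratio).
"""

import numpy as np

from eegskill.spectral import averaged_periodogram, band_powers, db_normalize

fs = 128.0
tone = np.sin(2 * np.pi * 10.0 * np.arange(int(20 * fs)) / fs)
bp = band_powers(averaged_periodogram(tone, fs))
print("relative band powers of a pure 10 Hz tone:")
for band in ("theta", "alpha", "beta", "gamma"):
    print(f"  {band:6s} {bp[band]:.4f}")
print("alpha (8-12 Hz) captures essentially all of the tone's power.\n")

for ratio in (1.0, 2.0, 3.0, 10.0):
    print(f"task/baseline power ratio {ratio:5.1f}  ->  {db_normalize(ratio, 1.0):7.4f} dB")
print("0 dB means no change from rest; ~4.77 dB is a tripling of band power.")
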