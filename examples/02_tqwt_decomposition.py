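"""Decompose a window into TQWT sub-bands and verify perfect reconstruction.

The tunable-Q wavelet transform with Q=1, r=3, J=8 splits an 868-sample
window into 9 sub-bands, band 1 holding the highest frequencies.  Sub-band
energies sum to the signal energy and the synthesis bank inverts the
analysis bank to machine precision.
"""

import numpy as np

from ictal import (SyntheticSpec, TQWTParams, WindowSpec, decompose,
                   generate_dataset, reconstruct, segment_windows,
                   subband_center_frequencies)

record = generate_dataset(SyntheticSpec(n_per_class=1, seed=0))[0]
window = segment_windows(record, WindowSpec(5.0))[0]

params = TQWTParams(Q=1, r=3, J=8)
sb = decompose(window, params)
fc = subband_center_frequencies(params, record.sampling_rate)
energies = sb.energies()

print(f"{'band':>4} {'length':>7} {'center Hz':>10} {'energy %':>9}")
for j, (band, f, e) in enumerate(zip(sb.bands, fc, energies), start=1):
    print(f"{j:>4} {band.size:>7} {f:>10.2f} {100 * e / energies.sum():>9.2f}")

x = window.samples
err = np.max(np.abs(x - reconstruct(sb))) / np.max(np.abs(x))
print(f"\nround-trip relative error: {err:.2e}")
print(f"energy conservation: sum(band)/signal = "
      f"{energies.sum() / np.sum(x**2):.12f}")
# Band centers fall geometrically (ratio alpha = 2/3); for an AR(2)
# background resonant near 10 Hz most energy sits in the mid bands.
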