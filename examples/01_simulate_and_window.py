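"""Simulate a labeled EEG-like dataset and cut it into analysis windows.

Builds the default two-class dataset (interictal-like AR(2) background vs
ictal-like 3 Hz spike-wave discharges), band-pass filters one segment, and
shows the window/sub-window geometry used throughout the pipeline.
"""

from ictal import (FilterSpec, SyntheticSpec, WindowSpec, bandpass,
                   generate_dataset, segment_windows, subwindow_for_cnn)

records = generate_dataset(SyntheticSpec(n_per_class=3, seed=0))
print(f"{len(records)} segments of {len(records[0])} samples "
      f"at {records[0].sampling_rate} Hz")

seg = records[-1]  # an ictal-like segment
filtered = bandpass(seg, FilterSpec(0.5, 40.0, order=4))
windows = segment_windows(filtered, WindowSpec(5.0))
sub = subwindow_for_cnn(windows[0])
print(f"segment '{seg.source_id}' -> {len(windows)} windows of "
      f"{len(windows[0])} samples; each window -> {sub.shape[0]} "
      f"sub-windows of {sub.shape[1]} samples")
# A 4097-sample segment at 173.6 Hz yields 4 non-overlapping 5 s windows of
# 868 samples; each window splits into 33 half-overlapping 50-sample
# sub-windows for the convolutional branch of the fusion classifier.
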