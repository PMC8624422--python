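"""Extract the handcrafted feature battery from one analysis window.

Shows the full default vector (27 features x 9 sub-bands + 27 raw = 270
values) and prints a few interpretable entries: ictal-like windows carry
more line energy and lower entropy than the irregular background.
"""

from ictal import (FeatureConfig, SyntheticSpec, WindowSpec, bandpass,
                   extract_features, generate_dataset, segment_windows)

records = generate_dataset(SyntheticSpec(n_per_class=1, seed=0))
by_label = {r.label: segment_windows(bandpass(r), WindowSpec(5.0))[0]
            for r in records}

fv = extract_features(by_label["interictal"])
print(f"default feature vector: {fv.values.size} values "
      f"({fv.n_imputed} degenerate cells imputed to 0)")

show = ["std__raw", "iwmf__raw", "spectral__raw", "sampen__raw",
        "fuzzen__raw", "higuchi__raw", "pe__raw"]
print(f"\n{'feature':>14} {'interictal':>12} {'ictal':>12}")
cache = {lbl: extract_features(w) for lbl, w in by_label.items()}
for name in show:
    row = []
    for lbl in ("interictal", "ictal"):
        v = cache[lbl]
        row.append(v.values[v.names.index(name)])
    print(f"{name:>14} {row[0]:>12.4f} {row[1]:>12.4f}")
# The ictal-like window shows larger amplitude (std), a spectral mean pulled
# toward the 3 Hz discharge (iwmf), and lower spectral/sample/permutation
# entropy: the discharge is more regular than the background.
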