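#!/usr/bin/env python
"""One complete synthetic study: simulate, analyze, characterize.

Simulates a 4 h two-wavelength recording with 60 interictal events driving a
bilateral, left-dominant hemodynamic response (onset -5 s, duration 22 s,
single-event channel peak at half the in-band noise sd), runs the full
pipeline (preprocess -> epoch -> ReML-frozen tomographic reconstruction ->
HbO cluster permutation test against 60 control markers), and reports the
significant clusters and the recovered response parameters.

Writes results/detection/{clusters.tsv,manifest.json,recovered.json}.
"""

import json

from nirsdot.harness import build_toy_scene, run_recovery_dataset

scene = build_toy_scene()
res = run_recovery_dataset(scene, seed=2024, n_perm=400)

out = {k: res[k] for k in (
    "detected", "n_sig_clusters", "affected_strength", "unaffected_strength",
    "onset_s", "duration_s", "peak_s", "true_onset_s", "true_duration_s",
)}
import pathlib

pathlib.Path("results/detection").mkdir(parents=True, exist_ok=True)
pathlib.Path("results/detection/recovered.json").write_text(json.dumps(out, indent=2))

print(f"significant clusters: {res['n_sig_clusters']} "
      f"(true-VOI overlap: {res['detected']})")
print(f"cluster strength, affected vs unaffected hemisphere: "
      f"{res['affected_strength']:.0f} vs {res['unaffected_strength']:.0f}")
print(f"recovered onset {res['onset_s']:.2f} s (truth {res['true_onset_s']:.1f}), "
      f"duration {res['duration_s']:.2f} s (truth {res['true_duration_s']:.1f})")
print("wrote results/detection/recovered.json")
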