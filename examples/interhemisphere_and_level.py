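"""Interhemispheric pairing and per-ROI sound-level decoding.

The hemisphere comparison reduces the 5 mirrored ROI pairs to the member
ipsi- or contralateral to the stimulated side and decodes -90 vs +90 deg.
Sound-level decoding asks, ROI by ROI, whether 48 vs 58 dB is separable
(it is not, with the default zero level effect).
"""

import numpy as np

import nirsloc as nl

rec, _, _ = nl.simulate_session(
    nl.SimulationConfig(seed=42, effect=nl.lateral_effect())
)
tt = nl.preprocess_recording(rec)
contrast = nl.ContrastSpec(nl.Condition(-90, 58), nl.Condition(90, 58),
                           name="-90/+90@58")

lateral_rows = [i for i, (loc, db) in enumerate(tt.labels)
                if loc in (-90, 90) and db == 58]
lat = tt.select_trials(lateral_rows)
for side in ("ipsi", "contra"):
    paired = nl.pair_hemispheres(lat, side=side)
    res = nl.loocv_svm(nl.extract_features(paired), contrast)
    print(f"{side:6s} hemisphere decoder: best accuracy {res.best_accuracy:.2f}")

ft = nl.extract_features(tt)
per_roi = nl.sound_level_decoding(ft, location_deg=-90)
accs = [r.best_accuracy for r in per_roi.values()]
print(f"sound level 48 vs 58 dB at -90 deg, per-ROI best accuracy: "
      f"mean {100 * np.mean(accs):.1f}% (max {100 * max(accs):.0f}%)")
# The generator gives 48 and 58 dB identical responses, so per-ROI level
# accuracies hover at the chance level of the best-dim statistic (single
# subjects fluctuate; the 25-subject group mean stays below the 70% margin
# while direction contrasts sit above it).
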