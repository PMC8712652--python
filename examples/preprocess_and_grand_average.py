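"""Run the preprocessing chain and compute per-location grand averages.

The chain is: common average reference (removes the shared systemic
component), 4th-order Butterworth low-pass 0.2 Hz + high-pass 0.03 Hz
(removes cardiac, respiratory and drift noise), 10-s stimulus-locked
epochs baselined to the pre-stimulus second, then averaging channels into
10 regions of interest.
"""

import numpy as np

import nirsloc as nl

rec, _, _ = nl.simulate_session(
    nl.SimulationConfig(seed=42, effect=nl.lateral_effect())
)
tt = nl.preprocess_recording(rec)  # ROI-level TrialTensor
print(f"epochs: {tt.n_trials} trials x {tt.n_units} ROIs x {tt.n_samples} samples")

ga = nl.grand_average(tt, group_by="location")
t_peak = np.linspace(0, 10, tt.n_samples)
for loc in (-90, 0, 90):
    mean, sem = ga[(loc,)]
    roi9 = 8  # right superior temporal gyrus
    k = int(np.argmax(mean[roi9]))
    print(f"{loc:+4d} deg: right-STG max {mean[roi9, k]:+.4f} mM*mm "
          f"at {t_peak[k]:.1f} s (SEM {sem[roi9, k]:.4f})")
# Within the 10-s epoch the block response is still rising, so the maximum
# sits at the window edge; the amplitude ordering -90 > 0 > +90 on the
# right STG reflects the contralateral boost for -90 and the delayed
# ipsilateral response to +90.
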