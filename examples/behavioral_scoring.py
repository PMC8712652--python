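"""Score a behavioral session: RMS localization error and confusion counts.

Responses are loudspeaker indices on the 7-speaker arc (30-degree
spacing); the RMS error converts target/response mismatches to degrees.
"""

import nirsloc as nl
from nirsloc.behavior import response_matrix, rms_report

_, beh, _ = nl.simulate_session(
    nl.SimulationConfig(seed=42, confusion=nl.lateral_confusion(p_error=0.3))
)
rep = rms_report(beh)
print(f"RMS error 48 dB: {rep.rms_low_deg:5.2f} deg over {rep.n_low} trials")
print(f"RMS error 58 dB: {rep.rms_high_deg:5.2f} deg over {rep.n_high} trials")
print(f"RMS error all:   {rep.rms_all_deg:5.2f} deg over {rep.n_all} trials")

mat = response_matrix(beh)
print("target x response counts (rows: -90,-30,0,+30,+90; cols: speakers 1-7):")
print(mat)
# With the lateral-confusion model all errors sit at (row 1 -> speaker 2)
# and (row 5 -> speaker 6): +/-90-deg sources mistaken for +/-60 deg,
# each 30 deg off, so RMS = sqrt(k * 900 / n) for k errors in n trials.
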