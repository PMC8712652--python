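subject,rms_low_deg,rms_high_deg,rms_all_deg
S1,0,0,0
S2,0,0,0
S3,6,0,4.24
S4,0,0,0
S5,0,0,0
S6,0,0,0
S7,0,0,0
S8,0,0,0
S9,0,0,0
S10,0,0,0
S11,11.23,11.23,11.23
S12,0,0,0
S13,0,0,0
S14,0,4.24,3
S15,4.24,0,3
S16,0,0,0
S17,6,12.73,9.95
S18,0,0,0
S19,15.30,4.24,11.22
S20,0,0,0
S21,10.39,10.39,10.39
S22,7.35,10.39,8.49
S23,0,0,0
S24,0,4.24,3
S25,0,0,0
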