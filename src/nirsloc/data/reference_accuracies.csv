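block,intensity_db,pair,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10,S11,S12,S13,S14,S15,S16,S17,S18,S19,S20,S21,S22,S23,S24,S25
lateral,48,-90/0,80,70,70,75,70,60,75,80,70,60,75,65,75,75,80,65,70,75,70,65,60,75,70,70,65
lateral,48,0/+90,70,80,65,70,75,75,70,70,70,70,75,60,75,80,75,65,75,80,85,75,75,90,85,70,60
lateral,48,-90/+90,85,70,85,85,85,80,75,65,90,70,70,80,60,70,80,80,80,70,85,100,70,90,90,80,70
lateral,58,-90/0,65,85,75,65,65,75,65,85,85,70,70,70,70,75,70,70,70,85,70,80,75,80,80,70,70
lateral,58,0/+90,65,85,75,65,85,65,75,70,75,75,70,70,85,85,70,80,85,80,75,75,75,80,90,70,65
lateral,58,-90/+90,70,55,75,85,95,85,90,75,65,75,90,65,80,75,65,65,90,80,85,100,60,95,75,70,70
front30,48,-30/0,65,70,80,65,80,70,80,60,80,75,60,70,65,70,65,25,65,40,65,70,70,65,70,70,70
front30,48,0/+30,75,60,60,65,35,45,70,70,70,85,60,70,80,70,90,75,70,65,80,60,65,80,65,65,70
front30,48,-30/+30,65,70,60,60,80,0,70,65,65,65,60,70,60,65,60,5,70,75,60,50,70,70,80,60,45
front30,58,-30/0,65,60,65,75,80,75,80,60,65,65,65,60,65,70,65,70,75,75,65,60,75,70,65,70,75
front30,58,0/+30,70,80,50,65,70,65,65,65,55,70,70,70,80,65,75,70,40,35,85,65,60,70,65,75,60
front30,58,-30/+30,60,65,65,0,65,60,40,60,80,60,80,80,60,70,80,65,70,65,75,65,65,80,65,60,60
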