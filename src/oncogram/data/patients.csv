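patient_id,supplementary,underline_ambiguous
01,0,0
02,1,0
03,0,0
04,1,0
05,1,0
06,0,0
07,1,0
08,1,1
09,0,1
10,1,0
11,0,0
12,1,0
13,1,0
14,0,0
15,1,0
16,1,0
17,1,0
18,1,0
19,1,0
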