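patient_id,evaluation_index,outcome
01,1,PD
01,2,PD
01,3,PD
02,1,SD
02,2,SD
02,3,CR
03,1,PD
03,2,PD
03,3,PD
04,1,PR
04,2,SD
04,3,PD
05,1,SD
05,2,PD
05,3,PD
06,1,SD
06,2,SD
06,3,PD
07,1,SD
07,2,SD
07,3,CR
08,1,SD
08,2,PD
08,3,PD
09,1,PD
09,2,SD
09,3,SD
10,1,SD
10,2,SD
10,3,SD
11,1,SD
11,2,SD
11,3,SD
12,1,SD
12,2,PR
12,3,SD
13,1,SD
13,2,SD
13,3,SD
14,1,SD
14,2,SD
14,3,SD
15,1,PR
15,2,SD
15,3,PR
16,1,SD
16,2,SD
16,3,SD
17,1,PD
17,2,SD
17,3,SD
18,1,PR
18,2,PR
18,3,PR
19,1,SD
19,2,SD
19,3,PD
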