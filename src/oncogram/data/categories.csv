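patient_id,treatment,category,received
01,FU_FA,S,1
01,FOLFIRI,S,1
01,FOLFOX,S,0
02,FU_FA,S,0
02,FOLFIRI,S,0
02,FOLFOX,I,1
03,FU_FA,S,1
03,FOLFIRI,S,0
03,FOLFOX,S,0
04,FU_FA,R,0
04,FOLFIRI,I,0
04,FOLFOX,I,1
05,FU_FA,I,0
05,FOLFIRI,R,0
05,FOLFOX,R,1
06,FU_FA,I,0
06,FOLFIRI,ND,1
06,FOLFOX,ND,0
07,FU_FA,S,1
07,FOLFIRI,I,0
07,FOLFOX,I,0
08,FU_FA,I,0
08,FOLFIRI,I,1
08,FOLFOX,I,1
09,FU_FA,R,0
09,FOLFIRI,S,1
09,FOLFOX,S,1
10,FU_FA,I,0
10,FOLFIRI,R,0
10,FOLFOX,S,1
11,FU_FA,I,1
11,FOLFIRI,R,0
11,FOLFOX,I,0
12,FU_FA,I,0
12,FOLFIRI,I,1
12,FOLFOX,I,0
13,FU_FA,S,1
13,FOLFIRI,I,0
13,FOLFOX,I,0
14,FU_FA,I,1
14,FOLFIRI,I,0
14,FOLFOX,S,1
15,FU_FA,I,0
15,FOLFIRI,R,0
15,FOLFOX,R,1
16,FU_FA,I,0
16,FOLFIRI,R,0
16,FOLFOX,R,1
17,FU_FA,I,0
17,FOLFIRI,I,0
17,FOLFOX,R,1
18,FU_FA,R,0
18,FOLFIRI,S,0
18,FOLFOX,I,1
19,FU_FA,R,1
19,FOLFIRI,I,0
19,FOLFOX,I,0
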