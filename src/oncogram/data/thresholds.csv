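treatment,median,minimum,maximum,q25,q75
FU_FA,1.343,0.895,2.102,1.029,1.701
FOLFIRI,1.633,0.788,2.883,1.186,1.965
FOLFOX,1.787,1.147,3.613,1.579,2.090
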