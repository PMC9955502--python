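run,W1,W2,W3,W4,W5,W6,W7,W8,W9,W10,W11
ANN1,1,1,1,1,1,1,1,1,1,1,1
ANN2,1,1,1,1,1,2,2,2,2,2,2
ANN3,1,1,2,2,2,1,1,1,2,2,2
ANN4,1,2,1,2,2,1,2,2,1,1,2
ANN5,1,2,2,1,2,2,1,2,1,2,1
ANN6,1,2,2,2,1,2,2,1,2,1,1
ANN7,2,1,2,2,1,1,2,2,1,2,1
ANN8,2,1,2,1,2,2,2,1,1,1,2
ANN9,2,1,1,2,2,2,1,2,2,1,1
ANN10,2,2,2,1,1,1,1,2,2,1,2
ANN11,2,2,1,2,1,2,1,1,1,2,2
ANN12,2,2,1,1,2,1,2,1,2,2,1
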