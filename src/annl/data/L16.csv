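run,W1,W2,W3,W4,W5,W6,W7,W8,W9,W10,W11,W12,W13,W14,W15
ANN1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
ANN2,1,1,1,1,1,1,1,2,2,2,2,2,2,2,2
ANN3,1,1,1,2,2,2,2,1,1,1,1,2,2,2,2
ANN4,1,1,1,1,2,2,2,2,2,2,2,1,1,1,1
ANN5,1,2,2,1,1,2,2,1,1,2,2,1,1,2,2
ANN6,1,2,2,1,1,2,2,2,2,1,1,2,2,1,1
ANN7,1,2,2,2,2,1,1,1,1,2,2,2,2,1,1
ANN8,1,2,2,2,2,1,1,2,2,1,1,1,1,2,2
ANN9,2,1,2,1,2,1,2,1,2,1,2,1,2,1,2
ANN10,2,1,2,1,2,1,2,2,1,2,1,2,1,2,1
ANN11,2,1,2,2,1,2,1,1,2,1,2,2,1,2,1
ANN12,2,1,2,2,1,2,1,2,1,2,1,1,2,1,2
ANN13,2,2,1,1,2,2,1,1,2,2,1,1,2,2,1
ANN14,2,2,1,1,2,2,1,2,1,1,2,2,1,1,2
ANN15,2,2,1,2,1,1,2,1,2,2,1,2,1,1,2
ANN16,2,2,1,2,1,1,2,2,1,1,2,1,2,2,1
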