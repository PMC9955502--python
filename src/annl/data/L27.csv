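run,W1,W2,W3,W4,W5,W6,W7,W8,W9,W10,W11,W12,W13
ANN1,1,1,1,1,1,1,1,1,1,1,1,1,1
ANN2,1,1,1,1,2,2,2,2,2,2,2,2,2
ANN3,1,1,1,1,3,3,3,3,3,3,3,3,3
ANN4,1,2,2,2,1,1,1,2,2,2,3,3,3
ANN5,1,2,2,2,2,2,2,3,3,3,1,1,1
ANN6,1,2,2,2,1,1,1,3,3,3,2,2,2
ANN7,1,3,3,3,1,1,1,3,3,3,2,2,2
ANN8,1,3,3,3,2,2,2,1,1,1,3,3,3
ANN9,1,3,3,3,3,3,3,2,2,2,1,1,1
ANN10,2,1,2,3,1,2,3,1,2,3,1,2,3
ANN11,2,1,2,3,2,3,1,2,3,1,2,3,1
ANN12,2,1,2,3,3,1,2,3,1,2,3,1,2
ANN13,2,2,3,1,1,2,3,2,3,1,3,1,2
ANN14,2,2,3,1,2,3,1,3,1,2,1,2,3
ANN15,2,2,3,1,3,1,2,1,2,3,2,3,1
ANN16,2,3,1,2,1,2,3,3,1,2,2,3,1
ANN17,2,3,1,2,2,3,1,1,2,3,3,1,2
ANN18,2,3,1,2,3,1,2,2,3,1,1,2,3
ANN19,3,1,3,2,1,3,2,1,3,2,1,3,2
ANN20,3,1,3,2,2,1,3,2,1,3,2,1,3
ANN21,3,1,3,2,3,2,1,3,2,1,3,2,1
ANN22,3,2,1,3,1,3,2,2,1,3,3,2,1
ANN23,3,2,1,3,2,1,3,3,2,1,1,3,2
ANN24,3,2,1,3,3,2,1,1,3,2,2,1,3
ANN25,3,3,2,1,1,3,2,3,2,1,2,1,3
ANN26,3,3,2,1,2,1,3,1,3,2,3,2,1
ANN27,3,3,2,1,3,2,1,2,1,3,1,3,2
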