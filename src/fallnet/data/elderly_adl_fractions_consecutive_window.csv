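task,S1,S2,S3,S4,S5,S6,S7,S8,S9,S10
D01,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1
D02,5/5,5/5,5/5,5/5,5/5,NA,5/5,5/5,5/5,5/5
D03,5/5,5/5,5/5,5/5,5/5,NA,5/5,4/5,5/5,4/5
D04,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
D05,5/5,5/5,NA,5/5,3/5,NA,NA,NA,NA,5/5
D06,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5
D07,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5
D08,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5
D09,5/5,5/5,NA,5/5,5/5,NA,5/5,5/5,5/5,5/5
D10,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
D11,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1
D12,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1
D13,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5
D14,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,4/5
D15,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
D16,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5
D17,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1,1/1
D18,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5
D19,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5,5/5
D20,5/5,5/5,0/5,5/5,5/5,2/5,NA,5/5,5/5,5/5
D21,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
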