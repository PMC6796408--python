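variable,AGE,CTQ,ASA,ISA,CESD1,CESD2,CESD3,CESD4,CESD5,SMOKE,WC,BMI,SBP,DBP
AGE,1.00,-0.02,0.04,-0.19,-0.01,-0.09,-0.02,-0.07,-0.02,-0.15,0.09,0.08,0.40,0.24
CTQ,-0.02,1.00,0.35,0.34,0.32,0.27,0.37,0.34,0.17,0.24,0.19,0.15,0.05,0.04
ASA,0.04,0.35,1.00,0.16,0.13,0.14,0.27,0.16,0.13,0.16,0.05,0.04,0.01,-0.02
ISA,-0.19,0.34,0.16,1.00,0.28,0.18,0.21,0.31,0.17,0.27,0.07,0.05,-0.10,-0.10
CESD1,-0.01,0.32,0.13,0.28,1.00,0.60,0.48,0.46,0.42,0.03,0.09,0.07,0.06,0.00
CESD2,-0.09,0.27,0.14,0.18,0.60,1.00,0.58,0.56,0.49,0.07,0.06,0.02,-0.08,-0.07
CESD3,-0.02,0.37,0.27,0.21,0.48,0.58,1.00,0.64,0.54,0.11,0.06,0.02,-0.11,-0.11
CESD4,-0.07,0.34,0.16,0.31,0.46,0.56,0.64,1.00,0.54,0.13,0.01,-0.03,-0.09,-0.12
CESD5,-0.02,0.17,0.13,0.17,0.42,0.49,0.54,0.54,1.00,0.09,0.18,0.11,-0.05,0.02
SMOKE,-0.15,0.24,0.16,0.27,0.03,0.07,0.11,0.13,0.09,1.00,-0.06,-0.10,-0.05,-0.05
WC,0.09,0.19,0.05,0.07,0.09,0.06,0.06,0.01,0.18,-0.06,1.00,0.89,0.39,0.46
BMI,0.08,0.15,0.04,0.05,0.07,0.02,0.02,-0.03,0.11,-0.10,0.89,1.00,0.35,0.45
SBP,0.40,0.05,0.01,-0.10,0.06,-0.08,-0.11,-0.09,-0.05,-0.05,0.39,0.35,1.00,0.66
DBP,0.24,0.04,-0.02,-0.10,0.00,-0.07,-0.11,-0.12,0.02,-0.05,0.46,0.45,0.66,1.00
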