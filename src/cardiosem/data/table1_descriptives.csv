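variable,mean,sd,n
AGE,39.4,9.8,227
CTQ,35.6,16.0,227
ASA,0.387665,0.487218,227
ISA,53.0,19.4,227
CESD1,24.2,13.0,227
CESD2,21.6,13.5,227
CESD3,19.1,13.1,227
CESD4,18.4,13.0,227
CESD5,18.5,13.0,227
SMOKE,1.039648,0.835984,227
WC,34.8,6.5,227
BMI,27.8,6.7,227
SBP,118.9,15.5,227
DBP,74.3,9.5,227
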