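drug,adjunct,adjunct_dose,ed50,sem,n
LCM,,0,8.27,1.20,16
LCM,IMP,25,6.52,0.88,16
LCM,IMP,50,3.38,0.93,16
OXC,,0,9.72,1.07,24
OXC,IMP,25,6.62,0.96,16
OXC,IMP,50,4.80,0.81,16
PGB,,0,197.6,12.6,24
PGB,IMP,25,165.0,12.1,24
PGB,IMP,50,134.6,11.8,16
TPM,,0,90.05,10.54,24
TPM,IMP,25,74.84,7.52,16
TPM,IMP,50,54.14,6.09,24
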