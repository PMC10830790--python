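drug,asm_dose,group,mean,sd,n
LCM,3.38,vehicle,0.252,0.011,8
LCM,3.38,IMP50,0.248,0.015,8
OXC,4.80,vehicle,0.921,0.052,8
OXC,4.80,IMP50,0.937,0.061,8
PGB,134.6,vehicle,64.87,2.51,8
PGB,134.6,IMP50,65.19,2.62,8
TPM,54.14,vehicle,6.861,0.442,8
TPM,54.14,IMP50,7.014,0.483,8
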