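variable,group,mean,sd,n,printed_p
Tumor diameter (cm),abortion,13.89,6.92,32,>0.05
Tumor diameter (cm),live_birth,12.36,7.68,105,>0.05
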