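characteristic,category,abortion,live_birth,printed_p
Reproductive history,Unipara,14,53,>0.05
Reproductive history,Multipara,18,52,>0.05
FIGO stage,1,22,78,>0.05
FIGO stage,>1,10,27,>0.05
Surgical indication,Emergency,6,12,>0.05
Surgical indication,Select,26,93,>0.05
GA of detection,Prepregnancy,0,8,0.026
GA of detection,1st trimester,22,42,0.026
GA of detection,2nd trimester,10,55,0.026
GA of surgery,1st trimester,21,2,0
GA of surgery,2nd trimester,11,19,0
GA of surgery,3rd trimester,0,82,0
GA of surgery,Postpartum,0,2,0
Surgery,Conservative surgery,8,48,>0.05
Surgery,Fertility-sparing surgery,19,35,>0.05
Surgery,Radical surgery,5,22,>0.05
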