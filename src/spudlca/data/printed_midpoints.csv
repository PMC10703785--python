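pathway,duration_weeks,category,value,unit
BL-FG,2,FEW,0.53,"kg 1,4-DCB"
BL-FG,2,ME,0.64,"kg 1,4-DCB"
BL-FG,2,GW,27.1,kg CO2 eq
BL-US,0,FEW,9.16E-02,"kg 1,4-DCB"
BL-US,0,ME,9.57E-02,"kg 1,4-DCB"
BL-US,0,GW,3.12,kg CO2 eq
FR-US,0,FEW,2.81,"kg 1,4-DCB"
FR-FG,5,FEW,4.03,"kg 1,4-DCB"
FR-ID,5,FEW,4.76,"kg 1,4-DCB"
FR-CP,5,FEW,5.67,"kg 1,4-DCB"
FR-CP,5,ME,7.03,"kg 1,4-DCB"
FR-CP,5,GW,2.91E+02,kg CO2 eq
BK-FG,5,FPM,5.95E-03,kg PM2.5 eq
BK-FG,5,FET,1.31E-03,kg P eq
BK-FG,5,HNCT,1.65E+00,"kg 1,4-DCB"
BK-FG,5,TAD,1.06E-02,kg SO2 eq
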