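pathway,duration_weeks,calories,calories_sd,Ca,Ca_sd,P,P_sd,K,K_sd,Na,Na_sd,Al,Al_sd,Cu,Cu_sd,Fe,Fe_sd,Mg,Mg_sd,Mn,Mn_sd,S,S_sd
FR-US,0,5143,1,302,2,1505,9,6964,20,141,3,8.9,0.2,2.8,0.2,9.0,0.1,612,4,15.0,0.2,1133,4
FR-FG,2,4555,2,373,1,2395,5,9509,10,163,3,7.9,0.4,1.4,0.7,11.2,0.4,660,4,17.6,0.4,985,1
FR-ID,2,4744,7,369,1,1188,2,7864,20,89,0.2,7.5,0.1,1.9,0.3,6.3,0.5,629,3,13.7,0.1,828,1
FR-CP,2,5055,1,372,4,1623,8,7671,20,128,2,7.4,0.1,1.7,0.3,9.1,0.8,636,5,15.0,0.2,942,4
FR-FG,5,4499,4,368,0.0,1814,0.4,7079,3,117,0.3,8.2,0.0,1.4,0.0,7.7,0.5,644,4,14.5,0.1,844,1
FR-ID,5,4761,2,498,1,2052,2,8932,4,114,1,8.7,0.5,2.0,0.1,9.5,0.8,786,2,15.0,0.2,1022,3
FR-CP,5,4369,1,567,2,2119,2,11483,7,142,0.4,7.3,0.3,2.4,0.2,11.4,0.4,858,2,14.8,0.2,1088,3
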