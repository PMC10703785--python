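pathway,duration_weeks,calories,calories_sd,Ca,Ca_sd,P,P_sd,K,K_sd,Na,Na_sd,Al,Al_sd,Cu,Cu_sd,Fe,Fe_sd,Mg,Mg_sd,Mn,Mn_sd,S,S_sd
BK-US,0,3669,0.1,416,1,1544,1,10345,6,235,0.1,8.2,0.1,2.2,0.1,7.7,0.2,745,1,13.4,0.1,899,1
BK-FG,2,3732,0.2,380,2,2486,1,11396,0.1,131,0.0,8.0,0.2,1.8,0.2,7.9,0.4,711,2,14.9,0.2,844,3
BK-ID,2,3697,0.5,427,1,1396,1,8064,20,129,1,7.7,0.1,1.7,0.1,6.3,0.1,838,0.2,14.1,0.0,903,0.3
BK-CP,2,3714,0.5,380,0.2,1629,6,9706,5,118,1,8.1,0.4,1.7,0.2,6.2,0.2,662,0.4,14.4,0.1,926,2
BK-FG,5,3637,0.1,566,1,2247,5,12822,20,198,0.1,8.5,0.3,1.8,0.1,8.5,0.6,976,3,15.0,0.1,1023,3
BK-ID,5,3646,0.2,640,1,3011,3,13275,6,141,1,9.3,0.1,2.4,0.1,13.9,0.3,1112,1,17.2,0.2,1260,3
BK-CP,5,3622,0.1,549,2,1820,2,10033,10,130,1,8.3,0.1,2.2,0.1,10.0,0.1,822,1,14.9,0.0,1000,2
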