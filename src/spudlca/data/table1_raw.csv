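pathway,duration_weeks,calories,calories_sd,Ca,Ca_sd,P,P_sd,K,K_sd,Na,Na_sd,Al,Al_sd,Cu,Cu_sd,Fe,Fe_sd,Mg,Mg_sd,Mn,Mn_sd,S,S_sd
RW-US,0,3668,0.4,489,6,1803,1,12159,7,270,4,9.5,0.1,2.3,0.1,10.7,0.3,886,0.1,15.2,0.1,1278,1
RW-FG,2,3656,0.5,519,3,2709,3,9382,30,217,1,9.2,0.1,2.1,0.2,12.0,0.2,709.5,0.4,20.8,1,1139,1
RW-ID,2,3630,0.4,543,1,1603,20,10595,50,136,1,8.8,0.1,2.3,0.1,6.3,0.5,765,3,14.7,0.1,1080,1
RW-CP,2,3689,0.1,344,2,1627,5,5506,2,138,1,8.9,0.1,<1.7,,8.6,0.5,656.5,1,15.6,0.1,1150,1
RW-FG,5,3565,0.4,478,0.4,1967,3,13273,0.1,174,0.3,7.9,0.5,1.7,0.1,7.3,1,821,2,14.8,0.2,846,1
RW-ID,5,3628,1,623,2,2511,10,11879,10,144,1,8.5,0.1,2.3,1,11.3,1,1048,2,16.2,0.2,1134,3
RW-CP,5,3607,1,527,2,3066,10,17917,10,144,2,7.5,0.1,2.8,0.1,11.7,1,1034,3,15.0,0.3,1250,2
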