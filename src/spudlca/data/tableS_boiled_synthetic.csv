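pathway,duration_weeks,calories,calories_sd,Ca,Ca_sd,P,P_sd,K,K_sd,Na,Na_sd,Al,Al_sd,Cu,Cu_sd,Fe,Fe_sd,Mg,Mg_sd,Mn,Mn_sd,S,S_sd
BL-US,0,3650.0,0.5,471,1.5,1637.2,5.4,7897.9,36.5,159.1,0.8,9,0.1,2.1,0.1,9.3,0.1,862.4,2.7,14.4,0.1,1154,3.8
BL-FG,2,3638.0,0.5,484.2,1.6,2483.2,8.1,6065.7,28.1,129.5,0.7,8.8,0.1,1.9,0.1,10.9,0.1,660.6,2.1,19.1,0.1,1057.5,3.4
BL-ID,2,3612.0,0.5,520.5,1.6,1393,4.8,6661.4,31.8,82.8,0.4,8.2,0.1,2.1,0.1,5.6,0.1,694.2,2.3,14.2,0.1,959.9,3.2
BL-CP,2,3671.0,0.5,330,1,1368.4,4.9,3679.2,16.5,82.6,0.4,8.3,0.1,<1.5,0.1,8,0.1,609.2,2,14.4,0.1,1062.3,3.5
BL-FG,5,3547.0,0.5,441.6,1.4,1730.7,5.9,8512.1,39.8,104.6,0.5,7.4,0.1,1.6,0.1,6.6,0.1,779.2,2.5,13.4,0.1,772.8,2.5
BL-ID,5,3610.0,0.5,584.2,1.9,2178.6,7.5,7559.8,35.6,89.7,0.4,8.1,0.1,2,0.1,10.5,0.1,931.1,3.1,15.4,0.1,1025.5,3.4
BL-CP,5,3589.0,0.5,500,1.6,2754.9,9.2,11438.3,53.8,86.1,0.4,7.2,0.1,2.5,0.1,10.4,0.1,964.3,3.1,13.5,0.1,1122.8,3.8
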