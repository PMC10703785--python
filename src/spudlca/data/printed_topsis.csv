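context,pathway,rank,score
environment,BL-CP,1,0.875
environment,BK-US,2,0.861
environment,BK-FG,3,0.857
nutrition,BL-FG,1,0.61
nutrition,BL-CP,2,0.55
nutrition,BK-US,3,0.53
equal,BL-CP,1,0.65
equal,BK-US,2,0.64
equal,BK-FG,3,0.62
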