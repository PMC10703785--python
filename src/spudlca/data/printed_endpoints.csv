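pathway,duration_weeks,human_health,ecosystems,resources
BL-FG,2,2.73E-04,2.00E-06,3.62
FR-CP,5,5.93E-04,3.22E-06,1.06E+01
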