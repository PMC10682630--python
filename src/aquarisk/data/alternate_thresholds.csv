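parameter,threshold_mg_kg_day,source,note
NO3,3.7,WHO-EFSA,acceptable daily intake
F,0.05,EFSA,adequate intake; covers all exposure sources
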