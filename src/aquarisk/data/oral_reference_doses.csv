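parameter,rfd_mg_kg_day,source,note
NO3,1.6,USEPA,
F,0.04,USEPA,
Ag,0.005,USEPA,magnitude corrected from an inconsistent source-table exponent
Ba,0.2,USEPA,
Cr,1.5,USEPA,total chromium
Fe,0.7,USEPA,
Mn,0.024,USEPA,
Sr,0.6,USEPA,
Zn,0.3,USEPA,
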