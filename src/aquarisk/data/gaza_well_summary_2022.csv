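parameter,units,max,min,mean,median,sd,who_guideline,detection_limit,status,point_value,in_exposure,note
pH,pH,8.08,6.65,7.45,7.46,0.30,,,detected,,False,guideline is the range 6.5-9.5; not screenable as a single upper bound
EC,uS/cm,29600,709,5202,3750,5101,2000,,detected,,False,bulk salinity indicator
TDS,mg/L,18352,354.5,3261,2325,3187,1000,,detected,,False,bulk salinity indicator
Hardness,mgCaCO3/L,2434,82,467,398,322,200,,detected,,False,
Cl,mg/L,9491,91,1419,810,1797,250,,detected,,True,
NO3,mg/L,365,16,112,93,74,50,,detected,,True,
F,mg/L,2.6,0.2,1.1,1.1,0.53,1.5,,detected,,True,
Br,mg/L,76.5,0.03,3.54,0.25,12.76,2,,detected,,True,strongly right-skewed; moment matching overstates the median
PO4,mg/L,72,72,72,72,0,,0.01,point_source,72,True,single detected well; detection limit is a synthetic stand-in
SO4,mg/L,1537,7.8,177,119,199,250,,detected,,True,
HCO3,mg/L,557,132,294,275,87,,,detected,,False,no guideline value
Ca,mg/L,375,13,84,68.4,60,75,,detected,,True,
Mg,mg/L,400,10.7,58,46.8,46,50,,detected,,True,
Na,mg/L,430,22.3,180,176,101,50,,detected,,True,
K,mg/L,48,1.17,7.46,4.82,7.72,12,,detected,,True,
Ag,ug/L,2.1,1.7,1.9,1.9,0.13,100,,detected,,True,
Al,ug/L,0.02,0.02,0.02,0.02,0,200,0.02,all_censored,,False,below detection limit in every well
As,ug/L,16,16,16,16,0,10,16,all_censored,,False,below detection limit in every well
Ba,ug/L,417,17.9,146,143,90,1300,,detected,,True,
Cd,ug/L,0.3,0.3,0.3,0.3,0,3,0.3,all_censored,,False,below detection limit in every well
Co,ug/L,1.7,1.7,1.7,1.7,0,20,1.7,all_censored,,False,below detection limit in every well
Cr,ug/L,102,6.9,26,21.3,16.7,50,,detected,,True,total chromium
Cu,ug/L,18,18,18,18,0,2000,0.1,point_source,18,False,single detected well; detection limit is a synthetic stand-in
Fe,ug/L,430,0.13,68,87,57,300,,detected,,True,
Mn,ug/L,35.8,0.06,1.56,1.28,3.33,0.8,,detected,,True,guideline stored as printed; magnitude inconsistent with WHO practice
Ni,ug/L,15,15,15,15,0,70,15,all_censored,,False,below detection limit in every well
Pb,ug/L,3,3,3,3,0,10,3,all_censored,,False,below detection limit in every well
Sr,ug/L,12350,539,2521,1770,2049,,,detected,,True,no WHO guideline; ATSDR advisory 4 mg/L
Zn,ug/L,61.2,1.42,9.7,7.59,8.51,3000,,detected,,True,
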