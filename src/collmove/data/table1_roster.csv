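id,sex,age_class,age_years,rank_within_sex,focal_duration_s
TG,male,adult,9,1,55200
ZL,male,adult,12,2,55200
GS,male,adult,28,3,54600
BT,male,adult,20,4,55800
YH,female,adult,9,1,55200
Hhui,female,adult,7,2,54600
YM,female,adult,22,3,55800
TH,female,adult,9,4,55800
HH,female,adult,9,5,55800
TR,female,adult,8,6,55200
TT,female,adult,21,7,55200
YZ,female,adult,20,8,54600
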