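section,variable,level,outcome,count
person,age,age2064,firearm,263442
person,age,age65p,firearm,86992
person,age,age2064,nonfirearm,288611
person,age,age65p,nonfirearm,34614
person,sex,male,firearm,304064
person,sex,female,firearm,46370
person,sex,male,nonfirearm,225947
person,sex,female,nonfirearm,97278
person,urbanicity,metro,firearm,268617
person,urbanicity,nonmetro,firearm,81817
person,urbanicity,metro,nonfirearm,275018
person,urbanicity,nonmetro,nonfirearm,48207
exposure,drought,NONE,firearm,189690
exposure,drought,M2SD_WRS,firearm,44652
exposure,drought,S2ED_WRS,firearm,17683
exposure,drought,S2ED_IMP,firearm,18694
exposure,drought,M2SD_IMP,firearm,54774
exposure,drought,WET,firearm,22681
exposure,drought,NONE,nonfirearm,172041
exposure,drought,M2SD_WRS,nonfirearm,41651
exposure,drought,S2ED_WRS,nonfirearm,16042
exposure,drought,S2ED_IMP,nonfirearm,17443
exposure,drought,M2SD_IMP,nonfirearm,51249
exposure,drought,WET,nonfirearm,21552
frequency,drought,NONE,county_months,397666
frequency,drought,M2SD_WRS,county_months,89825
frequency,drought,S2ED_WRS,county_months,33258
frequency,drought,S2ED_IMP,county_months,35747
frequency,drought,M2SD_IMP,county_months,105913
frequency,drought,WET,county_months,45867
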