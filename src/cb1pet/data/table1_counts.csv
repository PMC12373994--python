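variable,group,count,n
male_sex,HC,9,16
male_sex,TC,25,27
male_sex,PTSD,10,19
veteran,HC,0,16
veteran,TC,24,27
veteran,PTSD,11,19
white_race,HC,10,16
white_race,TC,22,27
white_race,PTSD,16,19
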