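variable,group,n,mean,sd
age,HC,16,29.37,8.16
age,TC,27,45.78,13.90
age,PTSD,19,42.58,13.03
bmi,HC,16,25.76,4.88
bmi,TC,27,29.74,6.04
bmi,PTSD,19,30.133,5.79
injected_mass,HC,16,13.71,3.85
injected_mass,TC,27,14.22,3.34
injected_mass,PTSD,19,12.05,4.83
number_of_traumas,TC,24,5.29,3.3
number_of_traumas,PTSD,11,27.64,32.5
age_first_trauma,TC,21,16.52,7.1
age_first_trauma,PTSD,10,14.3,7.96
age_presenting_trauma,TC,24,29.4,9.37
age_presenting_trauma,PTSD,18,22.65,14.6
caps_total,TC,25,8.72,6.91
caps_total,PTSD,19,38.42,9.34
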