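variable,test,printed_stat,printed_df,check
age,anova,9.14,"2,59",True
bmi,anova,3.17,"2,59",True
male_sex,chi2,10.91,2,True
veteran,chi2,32.31,2,True
number_of_traumas,welch_t,2.27,10,True
age_first_trauma,welch_t,0.75,16,True
injected_mass,anova,1.85,"2,59",False
age_presenting_trauma,welch_t,1.59,25,False
caps_total,welch_t,11.26,29,False
white_race,chi2,3.66,2,False
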