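stage,temperature_c,mean_days,se_days
egg,15,76.20,0.05
egg,20,42.60,0.05
egg,23,31.03,0.09
egg,25,20.20,0.08
egg,30,10.40,0.05
egg,35,9.61,0.05
egg,37,9.80,0.08
nymph,20,194.39,
nymph,23,150.59,
nymph,25,82.05,
nymph,30,53.08,
nymph,35,52.40,
nymph,37,55.82,
pre_adult,20,20.36,0.03
pre_adult,23,19.06,0.09
pre_adult,25,14.12,0.09
pre_adult,30,3.35,0.11
pre_adult,35,2.82,0.11
pre_adult,37,3.85,0.15
egg_adult_female,20,254.23,4.07
egg_adult_female,23,196.16,0.60
egg_adult_female,25,116.87,0.65
egg_adult_female,30,66.80,0.29
egg_adult_female,35,65.88,0.34
egg_adult_female,37,68.50,1.54
egg_adult_male,20,256.46,4.62
egg_adult_male,23,206.26,0.89
egg_adult_male,25,115.85,0.77
egg_adult_male,30,66.87,0.27
egg_adult_male,35,63.75,0.58
egg_adult_male,37,66.17,1.54
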