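parameter,temperature_c,mean,se
total_fecundity,20,221.87,21.90
total_fecundity,23,838.24,17.23
total_fecundity,25,1182.83,52.05
total_fecundity,30,3415.98,71.27
total_fecundity,35,615.67,64.43
total_fecundity,37,156.88,19.2
apop,20,19.84,0.88
apop,23,12.66,0.13
apop,25,8.17,0.40
apop,30,2.00,0.19
apop,35,2.33,0.18
apop,37,2.25,0.19
oviposition_period,20,44.97,1.15
oviposition_period,23,45.94,0.23
oviposition_period,25,47.66,2.75
oviposition_period,30,58.82,1.95
oviposition_period,35,49.09,1.98
oviposition_period,37,16.94,0.88
pop,20,11.32,0.70
pop,23,10.24,0.21
pop,25,9.43,1.21
pop,30,1.98,0.07
pop,35,2.00,0.13
pop,37,1.81,0.26
male_longevity,20,94.00,4.58
male_longevity,23,91.06,0.25
male_longevity,25,89.49,2.49
male_longevity,30,72.28,1.11
male_longevity,35,58.23,0.60
male_longevity,37,28.44,1.67
female_longevity,20,76.13,1.02
female_longevity,23,68.84,0.46
female_longevity,25,65.26,3.64
female_longevity,30,62.80,1.97
female_longevity,35,53.42,1.97
female_longevity,37,21.00,0.92
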