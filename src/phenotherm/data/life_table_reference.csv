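temperature_c,rm,GRR,Ro,T,lambda,Dt
20,0.004,12.16,4.39,355.47,1.00,187.12
23,0.027,335.70,237.65,199.42,1.03,25.28
25,0.040,603.52,466.48,154.55,1.04,17.45
30,0.075,1616.65,1330.76,96.07,1.08,9.26
35,0.071,311.60,206.16,75.21,1.07,9.81
37,0.030,39.12,10.69,79.11,1.03,23.51
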