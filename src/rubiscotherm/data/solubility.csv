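# Henry-law solubility coefficients for CO2 and O2 in pure water, expressed
# as uM dissolved gas per ubar of partial pressure.
# Sources: CO2 from standard Henry constants (0.0339 mol L-1 atm-1 at 25 C;
# Carroll, Slupsky & Mather 1991, J Phys Chem Ref Data 20:1201); O2 from the
# fits of Benson & Krause 1984 (Limnol Oceanogr 29:620).
temp_c,co2_um_per_ubar,o2_um_per_ubar
0,0.075401,0.0021515
5,0.062670,0.0018850
10,0.052603,0.0016778
15,0.044905,0.0015001
20,0.038687,0.0013620
25,0.033457,0.0012435
30,0.029312,0.0011448
35,0.025857,0.0010560
40,0.022995,0.0009869
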