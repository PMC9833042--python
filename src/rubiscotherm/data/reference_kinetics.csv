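# Rubisco kinetic constants at 25 C, with the Arrhenius activation energy of
# each constant, for Arabidopsis grown at 10, 20 and 30 C air temperature.
# Treatment means (standard errors) from in vitro assays of activated Rubisco
# extracts; k_c and k_o are dissolved-phase Michaelis constants (uM), s_co is
# the CO2/O2 specificity factor (M M-1), kcat_co2 the carboxylation turnover
# rate per catalytic site (s-1). ea is in kJ mol-1.
label,parameter,value_25,se_25,ea_kj_mol,se_ea
10C,kcat_co2,3.31,0.09,54.2,0.83
10C,s_co,75.1,1.0,-23.7,1.0
10C,k_c,11.8,0.49,54.8,4.4
10C,k_o,275.6,7.5,5.47,0.94
20C,kcat_co2,3.11,0.08,52.7,11.9
20C,s_co,76.9,1.0,-22.3,0.37
20C,k_c,11.5,0.52,55.9,5.6
20C,k_o,276.1,13.3,8.81,4.56
30C,kcat_co2,2.78,0.10,48.7,1.7
30C,s_co,78.0,0.83,-19.9,0.48
30C,k_c,11.4,0.70,40.4,3.3
30C,k_o,259.7,35.7,5.94,1.94
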