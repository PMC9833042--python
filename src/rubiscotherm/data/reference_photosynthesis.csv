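# Leaf-level photosynthetic parameter means for cold (10C)- and warm
# (30C)-grown Arabidopsis, measured at cuvette temperatures of 10 C and 30 C
# (leaf temperatures 8.8 C and 27.4 C). These reference means define the
# default generating truth of the synthetic-data module.
#   a400           net assimilation at Ca = 400 umol mol-1 (umol CO2 m-2 s-1)
#   g_s            stomatal conductance to water vapour (mol H2O m-2 s-1)
#   kc21_invivo_um apparent in vivo Michaelis constant at 21% O2 (uM)
#   j_max          maximum electron transport rate (umol e- m-2 s-1)
#   v_cmax         maximum carboxylation rate (umol CO2 m-2 s-1)
#   r_d            day respiration, measured in the dark (umol CO2 m-2 s-1)
#   g_m            mesophyll conductance to CO2 (mol CO2 m-2 s-1)
#   rubisco_sites  leaf Rubisco catalytic-site content (umol sites m-2)
growth_label,meas_label,t_leaf_c,a400,g_s,kc21_invivo_um,j_max,v_cmax,r_d,g_m,rubisco_sites
10C,10,8.8,19.2,0.26,17.7,133.1,55.8,1.1,0.114,14.4
10C,30,27.4,13.2,0.20,54.9,190.6,108.1,3.6,0.142,14.4
30C,10,8.8,11.8,0.44,15.6,74.1,40.1,1.1,0.131,8.9
30C,30,27.4,14.7,0.37,31.7,138.8,100.9,2.6,0.204,8.9
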