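root_id,days_elapsed,volume_mL,wet_mass_g,density_g_per_mL,pct_water
1,5,1.790,0.035,0.019,90.52
2,5,2.302,0.059,0.025,95.04
3,5,5.940,0.063,0.011,94.24
4,10,1.000,0.119,0.119,97.06
5,10,6.370,0.240,0.038,96.42
6,10,3.563,0.262,0.073,97.36
7,15,7.704,0.333,0.043,97.45
8,15,3.352,0.148,0.044,98.17
9,15,6.655,0.187,0.028,96.52
10,20,73.420,0.956,0.013,96.82
11,20,69.090,0.929,0.013,96.35
12,20,31.250,0.590,0.019,96.97
13,25,116.740,1.772,0.015,97.97
14,25,17.290,0.696,0.040,98.09
15,25,46.020,1.149,0.025,97.53
16,30,68.230,1.180,0.017,97.79
17,30,,0.3414,,97.57
18,30,,1.7325,,97.71
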