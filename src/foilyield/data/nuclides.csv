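nuclide,half_life_value,half_life_unit,half_life_unc,gamma_energy_kev,gamma_intensity,intensity_unc,usable
Sc-47,3.3492,d,0.0006,159.381,0.683,0.004,true
Sc-46,83.79,d,0.04,889.277,0.999840,0.000010,true
Sc-46,83.79,d,0.04,1120.545,0.999870,0.000010,false
Sc-44m,58.61,h,0.10,271.251,0.867,,true
Sc-44m,58.61,h,0.10,1157.002,0.0123,,false
Sc-44g,4.0420,h,0.0425,1157.022,0.998867,0.000030,true
Sc-43,3.891,h,0.012,372.9,0.225,,true
V-48,15.974,d,0.003,983.525,0.9998,0.0004,true
V-48,15.974,d,0.003,1312.105,0.982,0.003,true
Ni-57,35.60,h,,1377.63,0.817,,true
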