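energy_mev,sigma_mb,sigma_unc_mb
22.4,148.7,6.3
26.3,180.1,7.5
29.0,162.8,6.8
31.3,134.0,5.6
33.1,116.6,4.9
35.6,99.3,4.2
39.3,85.6,3.6
42.2,80.4,3.5
44.6,77.8,3.4
51.3,73.4,3.1
53.5,72.3,3.1
59.7,69.5,3.0
67.9,66.2,2.9
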