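target_id,energy_mev,energy_unc_mev,Sc-47,Sc-47_unc,Sc-46,Sc-46_unc,Sc-44g,Sc-44g_unc,Sc-44m,Sc-44m_unc,Sc-43,Sc-43_unc,V-48,V-48_unc
Ti48-01,18.2,0.4,4.0,0.3,,,,,,,,,,
Ti48-02,22.7,0.9,11.9,1.1,,,11.5,1.2,3.4,0.3,,,64.5,5.7
Ti48-03,26.7,0.8,19.9,3.9,,,47.4,9.4,13.9,2.7,,,41.9,8.2
Ti48-04,29.3,0.8,24.1,2.3,,,49.9,5.0,16.3,1.6,,,31.4,3.0
Ti48-05,31.5,0.7,28.1,2.5,10.9,2.2,52.8,5.2,19.9,1.8,,,30.5,2.7
Ti48-06,33.0,0.8,23.9,2.2,18.0,2.0,43.9,4.2,17.3,1.6,,,27.8,2.5
Ti48-07,35.5,0.7,22.1,2.0,39.3,3.9,34.8,3.3,16.0,1.4,3.9,0.6,25.6,2.3
Ti48-08,37.6,0.7,22.4,2.0,48.9,4.8,25.1,2.5,12.6,1.1,8.3,0.9,24.6,2.2
Ti48-09,39.6,0.6,21.4,1.9,63.7,6.2,18.5,1.8,9.8,0.9,12.9,1.2,23.7,2.2
Ti48-10,42.0,0.7,20.6,1.8,67.9,6.2,13.3,1.9,6.9,0.6,16.2,2.2,19.9,1.7
Ti48-11,44.8,0.5,19.1,1.8,75.0,7.4,10.4,1.4,4.6,0.5,14.4,2.3,19.0,1.8
Ti48-12,51.4,0.8,19.5,1.7,65.9,6.0,8.4,0.8,4.0,0.4,11.0,1.1,17.8,1.6
Ti48-13,53.6,0.7,19.1,1.7,63.7,5.9,8.4,0.9,4.6,0.4,9.6,1.2,17.9,1.6
Ti48-14,59.9,0.7,18.7,1.7,53.7,5.1,12.7,1.3,8.1,0.7,6.5,0.8,13.2,1.2
Ti48-15,68.0,0.7,16.9,1.5,48.2,4.8,25.7,2.6,14.1,1.3,4.1,0.6,10.1,1.0
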