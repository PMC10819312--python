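t_irr_h,e_entry_mev,Sc-47,Sc-46,Sc-44g,Sc-44m,Sc-43
24,25,73,,447,39,
24,30,198,,1792,154,
24,35,364,4.8,3270,297,19.9
24,40,556,19.4,4232,412,289
80,25,196,,454,96,
80,30,529,,1820,381,
80,35,971,15.8,3320,736,20.2
80,40,1481,64,4298,1019,293
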