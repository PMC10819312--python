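product,threshold_mev,channel
Sc-47,11.687,"(p,2p)"
Sc-46,14.677,"(p,3He)"
Sc-44g,14.173,"(p,alpha+n)"
Sc-44m,14.450,"(p,alpha+n)"
Sc-43,23.084,"(p,6He)"
V-48,4.897,"(p,n)"
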