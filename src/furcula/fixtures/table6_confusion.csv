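predicted,Bound,Flap,Glide,Poor,Preflight,Soar
Bound,5,1,1,0,0,0
Flap,3,25,13,3,0,0
Glide,0,3,7,3,0,0
Poor,0,1,0,3,0,0
Preflight,0,0,0,0,5,1
Soar,0,1,4,0,2,9
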