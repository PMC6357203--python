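experiment,condition,n_red,n_green,d_rr,d_gg,d_rg
MCX1,initial,67,60,3,3,5
MCX2,initial,83,77,3,4,7
MCX3,initial,407,448,11,12,32
MCX4,initial,125,104,7,6,20
MCX5,initial,114,110,4,5,27
MCX6,initial,129,125,5,4,25
MCX1,cultured,171,167,28,22,8
MCX2,cultured,124,134,22,24,8
MCX3,cultured,157,151,18,19,9
MCX4,cultured,132,127,24,16,9
MCX5,cultured,126,127,19,15,9
MCX6,cultured,122,103,19,14,7
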