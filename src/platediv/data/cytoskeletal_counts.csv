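experiment,condition,n_red,n_green,d_rr,d_gg,d_rg
taxol,mock,164,144,21,16,10
taxol,treated,157,149,8,7,16
nocodazole,mock,168,166,15,18,7
nocodazole,treated,149,146,11,10,24
cytochalasin_d,mock,301,281,21,22,10
cytochalasin_d,treated,346,313,15,12,29
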