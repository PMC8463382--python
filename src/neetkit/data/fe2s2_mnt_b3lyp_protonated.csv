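bond,state,R_nm,K_r
FeX-S1,oxidized,0.228,31254.5
FeX-S2,oxidized,0.229,29497.2
FeX-SCys1,oxidized,0.232,33555.7
FeX-SCys2,oxidized,0.232,33095.4
FeY-S1,oxidized,0.221,46358.7
FeY-S2,oxidized,0.221,45145.4
FeY-SCys3,oxidized,0.233,31882.1
FeY-NHis,oxidized,0.218,16359.4
FeX-S1,reduced,0.226,36024.2
FeX-S2,reduced,0.227,35187.4
FeX-SCys1,reduced,0.240,23472.2
FeX-SCys2,reduced,0.240,23263.0
FeY-S1,reduced,0.230,30585.0
FeY-S2,reduced,0.231,29078.8
FeY-SCys3,reduced,0.242,17572.8
FeY-NHis,reduced,0.230,7740.4
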