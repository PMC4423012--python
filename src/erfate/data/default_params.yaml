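APO_T: 1.0
AUT_T: 1.0
ERSS_T: 1.0
J_aa: 0.05
J_ia: 0.2194
Omega: 100
k_fb: 350.0
ka_e: 0.1222
kaap: 0.23
kaau: 0.02
kaau_p: 0.65
ki_e: 1.79
kiap: 0.02
kiap_p: 0.1983
kiau: 0.0322
kiau_p: 1.8
n_steps: 2
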