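label,E_c,dG_R_bind,E_vdw,dMSA,dG_bind
K1L,-16.27,52.45,-54.68,-1043.38,-6.24
N39G,-16.10,62.87,-62.35,-966.47,-5.83
I40P,-30.56,50.21,-53.26,-1019.20,-6.43
T42N,-28.65,75.47,-69.25,-990.20,-6.58
N174D,-29.81,68.49,-70.49,-903.56,-7.44
D218V,-20.35,52.11,-40.36,-970.43,-5.10
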