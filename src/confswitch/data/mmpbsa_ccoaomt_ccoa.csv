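label,ELE_IN,VDW_IN,ELE_PB,VDW_SA,H,TdS
receptor,-7325.69,-964.62,-3044.21,68.97,,2627.37
ligand,-512.76,-4.52,-107.70,6.44,,104.88
complex,-7917.25,-1023.19,-3048.89,68.05,,2705.24
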