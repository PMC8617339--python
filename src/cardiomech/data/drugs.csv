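drug,channel,half_max_nM,hill,mode,a_max
# Repo-supplied multichannel table. Verapamil entries are representative
# values from the Kramer et al. multichannel patch dataset (I_CaL/I_Kr/I_Na
# block); the Bay-K 8644 EC50/Hill are the published agonist constants and
# its a_max is a fitted convenience constant (saturable doubling of I_CaL).
verapamil,I_CaL,202,1.1,block,0
verapamil,I_Kr,288,1.0,block,0
verapamil,I_Na,32500,1.0,block,0
bay_k_8644,I_CaL,17.3,1.25,agonist,1.0
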