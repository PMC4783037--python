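row,Fish,BioA,BioB,BioPhys,Phys
physical,0.32,0,0.31,0.26,0.28
chemical,0.23,0,0.31,0.21,0.44
biological,0.45,1,0.39,0.53,0.28
aggregation,add,Ø,mult,mult,add
synergy,1,Ø,0.25,0.5,1
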