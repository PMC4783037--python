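branch,expert,node,method
top,Fish,ecological_state,additive
top,BioB,ecological_state,multiplicative
top,BioPhys,ecological_state,multiplicative
top,Phys,ecological_state,additive
physical,Phys,physical_state,additive
physical,Phys,morphology_hydraulics,additive
physical,Phys,discharge,additive
physical,Phys,flood_dynamics,additive
physical,Phys,connectivity,additive
physical,assumed,longitudinal_connectivity,additive
physical,unattributed,physical_a7,additive
physical,P1,physical_m1,multiplicative
physical,P2,physical_m2,multiplicative
physical,P3,physical_m3,multiplicative
physical,P4,physical_m4,multiplicative
physical,P5,physical_m5,multiplicative
physical,P6,physical_m6,multiplicative
physical,P7,physical_m7,multiplicative
chemical,Phys,physico_chemical_state,additive
chemical,Phys,suspended_solids,additive
chemical,C1,chemical_m1,multiplicative
chemical,C2,chemical_m2,multiplicative
chemical,C3,chemical_m3,multiplicative
biological,BioA,beetle_density,additive
biological,B1,biological_m1,multiplicative
biological,B2,biological_m2,multiplicative
biological,B3,biological_m3,multiplicative
biological,B4,biological_m4,multiplicative
biological,B5,biological_m5,multiplicative
biological,B6,biological_m6,multiplicative
biological,B7,biological_m7,multiplicative
biological,B8,biological_m8,multiplicative
biological,B9,biological_m9,multiplicative
biological,B10,biological_m10,multiplicative
biological,B11,biological_m11,multiplicative
biological,B12,biological_m12,multiplicative
biological,B13,biological_m13,multiplicative
biological,B14,biological_m14,multiplicative
biological,B15,biological_m15,multiplicative
biological,B16,biological_m16,multiplicative
biological,B17,biological_m17,multiplicative
biological,B18,biological_m18,multiplicative
biological,B19,biological_m19,multiplicative
biological,B20,biological_m20,multiplicative
biological,B21,biological_m21,multiplicative
biological,B22,biological_m22,multiplicative
biological,B23,biological_m23,multiplicative
biological,B24,biological_m24,multiplicative
biological,B25,biological_m25,multiplicative
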