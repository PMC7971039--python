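group,property_1,property_2,property_3
A,hydrophobicity,hydrophilicity,mass
B,polarity,molecular_weight,melting_point
C,transfer_free_energy,buriability,bulkiness
D,solvation_free_energy,relative_mutability,residue_volume
E,volume,amino_acid_distribution,hydration_number
F,isoelectric_point,compressibility,chromatographic_index
G,unfolding_entropy_change,unfolding_enthalpy,unfolding_gibbs_energy
H,helix_n_terminal_power,helix_c_terminal_power,helix_middle_power
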