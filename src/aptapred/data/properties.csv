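residue,hydrophobicity,hydrophilicity,mass,polarity,molecular_weight,melting_point,transfer_free_energy,buriability,bulkiness,solvation_free_energy,relative_mutability,residue_volume,volume,amino_acid_distribution,hydration_number,isoelectric_point,compressibility,chromatographic_index,unfolding_entropy_change,unfolding_enthalpy,unfolding_gibbs_energy,helix_n_terminal_power,helix_c_terminal_power,helix_middle_power
A,0.62,-0.5,15.0,8.1,89.09,297,0.3,0.78,11.5,0.67,100,88.3,1.0,8.6,1.5,6.0,-25.5,0.5,24.0,10.9,8.5,1.29,1.2,1.42
C,0.29,-1.0,47.0,5.5,121.15,178,0.9,0.91,13.46,0.38,20,112.4,2.43,2.9,1.0,5.05,-32.8,-6.8,44.7,14.6,11.0,0.79,1.19,0.7
D,-0.9,3.0,59.0,13.0,133.1,270,-0.6,0.62,11.68,-1.2,106,110.8,2.78,5.5,6.0,2.77,-33.1,-8.2,31.2,12.6,8.5,1.51,0.66,1.01
E,-0.74,3.0,73.0,12.3,147.13,249,-0.7,0.54,13.57,-0.76,102,140.5,3.78,6.0,7.0,3.22,-36.2,-16.9,41.5,14.0,8.8,1.44,0.87,1.51
F,1.19,-2.5,91.0,5.2,165.19,284,0.5,0.85,19.8,2.3,41,189.0,5.89,3.6,0.0,5.48,-22.4,13.2,51.1,15.9,11.2,1.07,1.1,1.13
G,0.48,0.0,1.0,9.0,75.07,290,0.3,0.77,3.4,0.0,49,60.0,0.0,8.4,1.0,5.97,-27.0,0.0,23.7,10.5,7.1,1.64,1.77,0.57
H,-0.4,-0.5,81.0,10.4,155.16,277,-0.1,0.69,13.69,0.64,66,152.6,4.66,2.0,4.0,7.59,-31.1,-3.5,44.9,14.8,10.1,1.05,1.31,1.0
I,1.38,-1.8,57.0,5.2,131.17,284,0.7,0.88,21.4,1.9,96,168.5,4.0,4.5,1.0,6.02,-21.6,13.9,45.0,14.3,16.8,0.97,1.05,1.08
K,-1.5,3.0,72.0,11.3,146.19,224,-1.8,0.47,15.71,-0.57,56,175.6,4.77,6.6,4.5,9.74,-25.8,0.1,47.3,15.5,7.9,1.07,1.17,1.16
L,1.06,-1.8,57.0,4.9,131.17,337,0.5,0.85,21.4,1.9,40,168.5,4.0,7.4,1.0,5.98,-23.2,8.8,46.6,14.6,15.0,1.21,1.11,1.21
M,0.64,-1.3,75.0,5.7,149.21,283,0.4,0.83,16.25,2.4,94,162.2,4.43,1.7,1.0,5.74,-27.4,4.8,51.3,16.2,13.3,1.24,1.26,1.45
N,-0.78,0.2,58.0,11.6,132.12,236,-0.5,0.62,12.82,-0.6,134,125.1,2.95,4.3,2.0,5.41,-31.9,0.8,36.4,12.7,8.2,1.56,1.28,0.67
P,0.12,0.0,42.0,8.0,115.13,222,-0.3,0.64,17.43,1.2,56,122.2,2.72,5.2,3.0,6.3,-23.0,6.1,28.7,11.9,8.2,1.52,0.1,0.57
Q,-0.85,0.2,72.0,10.5,146.15,185,-0.7,0.58,14.45,-0.22,93,148.7,3.95,3.9,2.0,5.65,-32.9,-4.8,41.4,14.4,6.3,1.27,1.12,1.11
R,-2.53,3.0,100.0,10.5,174.2,238,-1.4,0.52,14.28,-2.1,65,181.2,6.13,4.9,3.0,10.76,-26.7,0.8,56.5,17.3,9.1,0.96,1.13,0.98
S,-0.18,0.3,31.0,9.2,105.09,228,-0.1,0.7,9.47,0.01,120,88.7,1.6,7.0,2.0,5.68,-29.3,1.2,26.6,11.3,7.4,1.7,0.96,0.77
T,-0.05,-0.4,45.0,8.6,119.12,253,-0.2,0.71,15.77,0.52,97,118.2,2.6,6.1,2.0,5.66,-27.3,2.7,31.0,12.3,8.8,1.2,0.75,0.83
V,1.08,-1.5,43.0,5.9,117.15,293,0.6,0.86,21.57,1.5,74,141.4,3.0,6.6,1.0,5.96,-21.0,2.7,38.5,13.2,12.0,0.91,0.95,1.06
W,0.81,-3.4,130.0,5.4,204.24,282,0.3,0.8,21.67,2.6,18,227.0,8.08,1.3,2.0,5.89,-24.1,14.9,60.0,18.1,9.9,1.11,1.21,1.08
Y,0.26,-2.3,107.0,6.2,181.19,344,-0.4,0.71,18.03,1.6,41,193.0,6.47,3.4,3.0,5.66,-24.9,6.1,51.7,16.4,8.8,0.73,1.05,0.69
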