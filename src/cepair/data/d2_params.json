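{
  "version": "1.0",
  "comment": "Grimme D2 pairwise dispersion constants: C6 coefficients in J nm^6 mol^-1 and van der Waals radii R_r in Å, with the sigmoidal damping steepness d and global prefactor s6. Combination rule: C6_ij = sqrt(C6_i * C6_j); R_r(ij) = R_i + R_j.",
  "s6": 1.0,
  "d": 20.0,
  "c6": {
    "H": 0.14, "He": 0.08,
    "Li": 1.61, "Be": 1.61, "B": 3.13, "C": 1.75, "N": 1.23, "O": 0.70,
    "F": 0.75, "Ne": 0.63,
    "Na": 5.71, "Mg": 5.71, "Al": 10.79, "Si": 9.23, "P": 7.84, "S": 5.57,
    "Cl": 5.07, "Ar": 4.61,
    "K": 10.80, "Ca": 10.80, "Sc": 10.80, "Ti": 10.80, "V": 10.80,
    "Cr": 10.80, "Mn": 10.80, "Fe": 10.80, "Co": 10.80, "Ni": 10.80,
    "Cu": 10.80, "Zn": 10.80,
    "Ga": 16.99, "Ge": 17.10, "As": 16.37, "Se": 12.64, "Br": 12.47,
    "Kr": 12.01,
    "Rb": 24.67, "Sr": 24.67, "Y": 24.67, "Zr": 24.67, "Nb": 24.67,
    "Mo": 24.67, "Tc": 24.67, "Ru": 24.67, "Rh": 24.67, "Pd": 24.67,
    "Ag": 24.67, "Cd": 24.67,
    "In": 37.32, "Sn": 38.71, "Sb": 38.44, "Te": 31.74, "I": 31.50,
    "Xe": 29.99
  },
  "r_vdw": {
    "H": 1.001, "He": 1.012,
    "Li": 0.825, "Be": 1.408, "B": 1.485, "C": 1.452, "N": 1.397,
    "O": 1.342, "F": 1.287, "Ne": 1.243,
    "Na": 1.144, "Mg": 1.364, "Al": 1.639, "Si": 1.716, "P": 1.705,
    "S": 1.683, "Cl": 1.639, "Ar": 1.595,
    "K": 1.485, "Ca": 1.474, "Sc": 1.562, "Ti": 1.562, "V": 1.562,
    "Cr": 1.562, "Mn": 1.562, "Fe": 1.562, "Co": 1.562, "Ni": 1.562,
    "Cu": 1.562, "Zn": 1.562,
    "Ga": 1.650, "Ge": 1.727, "As": 1.760, "Se": 1.771, "Br": 1.749,
    "Kr": 1.727,
    "Rb": 1.628, "Sr": 1.606, "Y": 1.639, "Zr": 1.639, "Nb": 1.639,
    "Mo": 1.639, "Tc": 1.639, "Ru": 1.639, "Rh": 1.639, "Pd": 1.639,
    "Ag": 1.639, "Cd": 1.639,
    "In": 1.672, "Sn": 1.804, "Sb": 1.881, "Te": 1.892, "I": 1.892,
    "Xe": 1.881
  }
}
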