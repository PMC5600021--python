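{
  "version": "1.0",
  "comment": "Isotropic atomic polarizabilities in atomic units. 'neutral' values follow the Thakkar & Lupinetti compilation for free atoms; 'cation'/'anion' entries are the monatomic-ion values used in the polarization term whenever a species is unambiguously a bare, non-covalently-bound ion (literature averages; the iodide value is extrapolated from the halide ion/atom ratio trend).",
  "neutral": {
    "H": 4.50, "He": 1.38,
    "Li": 164.0, "Be": 37.74, "B": 20.5, "C": 11.3, "N": 7.4, "O": 5.3,
    "F": 3.70, "Ne": 2.66,
    "Na": 162.9, "Mg": 71.22, "Al": 57.8, "Si": 37.3, "P": 25.0, "S": 19.6,
    "Cl": 14.57, "Ar": 11.1,
    "K": 291.1, "Ca": 157.9, "Sc": 97.0, "Ti": 100.0, "V": 87.0, "Cr": 83.0,
    "Mn": 68.0, "Fe": 62.0, "Co": 55.0, "Ni": 49.0, "Cu": 47.0, "Zn": 38.7,
    "Ga": 50.3, "Ge": 40.0, "As": 29.8, "Se": 26.2, "Br": 21.13, "Kr": 16.8,
    "Rb": 316.2, "Sr": 199.0, "I": 32.98, "Xe": 27.3, "Cs": 396.0, "Ba": 273.5
  },
  "cation": {
    "Li": 0.190, "Na": 0.986, "K": 5.4, "Rb": 9.1, "Cs": 15.7,
    "Be": 0.052, "Mg": 0.482, "Ca": 3.2, "Sr": 5.8, "Ba": 10.6
  },
  "anion": {
    "F": 7.25, "Cl": 21.2, "Br": 27.9, "I": 39.6
  }
}
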