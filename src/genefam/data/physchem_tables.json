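{
  "version": "1.0",
  "comment": "Average residue masses (Da), Bjellqvist-style pKa values as used by common web pI calculators, and Robinson-Robinson background amino-acid frequencies.",
  "residue_masses": {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132
  },
  "water_mass": 18.0153,
  "pka_positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
  "pka_negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
  "pka_nterm_by_residue": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
                           "T": 6.82, "V": 7.44, "E": 7.7},
  "pka_cterm_by_residue": {"D": 4.55, "E": 4.75},
  "background_frequencies": {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.064
  }
}
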