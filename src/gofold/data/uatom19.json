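{
  "name": "uatom19",
  "comment": "United-atom van der Waals radii (Angstrom). Carbons carrying implicit hydrogens use enlarged radii; the aliphatic CHn radius of 1.84 A anchors the methyl-methyl attractive range at lambda*alpha*(2*1.84) = 4.71 A for alpha=0.80, lambda=1.6.",
  "element_defaults": {
    "N": 1.65,
    "O": 1.52,
    "S": 1.85,
    "SE": 1.9,
    "P": 1.8
  },
  "carbon_radii": {
    "aliphatic_ch": 1.84,
    "aromatic_ch": 1.74,
    "bare": 1.7
  },
  "bare_carbons": {
    "*": ["C"],
    "ASP": ["CG"],
    "GLU": ["CD"],
    "ASN": ["CG"],
    "GLN": ["CD"],
    "ARG": ["CZ"],
    "PHE": ["CG"],
    "TYR": ["CG", "CZ"],
    "TRP": ["CG", "CD2", "CE2"],
    "HIS": ["CG"]
  },
  "aromatic_ch_carbons": {
    "PHE": ["CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CD1", "CD2", "CE1", "CE2"],
    "TRP": ["CD1", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CD2", "CE1"]
  }
}
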