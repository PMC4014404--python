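{
  "comment": "Region constants for human beta-2 microglobulin (deposited PDB numbering). Strand ranges follow the deposited secondary-structure assignment; the hydrophobic core is the standard 21-residue set.",
  "wt_strands": {
    "A": [[6, 11]],
    "B": [[21, 28]],
    "C": [[36, 41]],
    "Cp": [[44, 45]],
    "D": [[50, 51]],
    "E": [[64, 70]],
    "F": [[79, 83]],
    "G": [[91, 94]]
  },
  "dn6_strands": {
    "A": [[8, 11]],
    "B": [[21, 27]],
    "C": [[35, 41]],
    "Cp": [[44, 45]],
    "E": [[64, 70]],
    "F": [[78, 84]],
    "G": [[91, 94]]
  },
  "core": [[21, 94]],
  "hydrophobic_core_residues": [
    [7, "LEU"], [9, "VAL"], [23, "LEU"], [27, "VAL"], [30, "PHE"],
    [35, "ILE"], [37, "VAL"], [39, "LEU"], [40, "LEU"], [54, "LEU"],
    [56, "PHE"], [60, "TRP"], [62, "PHE"], [63, "TYR"], [64, "LEU"],
    [65, "LEU"], [70, "PHE"], [78, "TYR"], [82, "VAL"], [93, "VAL"],
    [95, "TRP"]
  ]
}
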