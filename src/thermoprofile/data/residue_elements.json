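{
  "comment": "Atomic composition (C,H,N,O,S) of amino-acid residues, i.e. free amino acid minus one water, v1. Peptide formula = sum(residues) + H2O.",
  "water": {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0},
  "residues": {
    "A": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 0},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1, "S": 0},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2, "S": 0},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3, "S": 0},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3, "S": 0},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2, "S": 0},
    "G": {"C": 2, "H": 3, "N": 1, "O": 1, "S": 0},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1, "S": 0},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1, "S": 0},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1, "S": 0},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1, "S": 0},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1, "S": 0},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1, "S": 0},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2, "S": 0},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2, "S": 0},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1, "S": 0},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2, "S": 0},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 0}
  }
}
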