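{
  "schema_version": 1,
  "comment": "Dissociation constants (pKa, pH units) of ionizable groups: alpha-amino (n_term), alpha-carboxyl (c_term) and the seven ionizable side chains. Values transcribed from the cited original publications; a side chain absent from 'side_chain' is treated as non-titratable under that set. Position-aware sets carry per-terminal-residue overrides.",
  "sets": {
    "EMBOSS": {
      "n_term": 8.6, "c_term": 3.6,
      "side_chain": {"C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1}
    },
    "DTASelect": {
      "n_term": 8.0, "c_term": 3.1,
      "side_chain": {"C": 8.5, "D": 4.4, "E": 4.4, "H": 6.5, "K": 10.0, "R": 12.0, "Y": 10.0}
    },
    "Solomon": {
      "n_term": 9.6, "c_term": 2.4,
      "side_chain": {"C": 8.3, "D": 3.9, "E": 4.3, "H": 6.0, "K": 10.5, "R": 12.5, "Y": 10.1}
    },
    "Sillero": {
      "n_term": 8.2, "c_term": 3.2,
      "side_chain": {"C": 9.0, "D": 4.0, "E": 4.5, "H": 6.4, "K": 10.4, "R": 12.0, "Y": 10.0}
    },
    "Rodwell": {
      "n_term": 8.0, "c_term": 3.1,
      "side_chain": {"C": 8.33, "D": 3.68, "E": 4.25, "H": 6.0, "K": 11.5, "R": 11.5, "Y": 10.07}
    },
    "Lehninger": {
      "n_term": 9.69, "c_term": 2.34,
      "side_chain": {"C": 8.33, "D": 3.86, "E": 4.25, "H": 6.0, "K": 10.5, "R": 12.4, "Y": 10.0}
    },
    "Dawson": {
      "n_term": 8.2, "c_term": 3.2,
      "side_chain": {"C": 8.3, "D": 3.9, "E": 4.3, "H": 6.0, "K": 10.5, "R": 12.0, "Y": 10.1}
    },
    "Grimsley": {
      "n_term": 7.7, "c_term": 3.3,
      "side_chain": {"C": 6.8, "D": 3.5, "E": 4.2, "H": 6.6, "K": 10.5, "R": 12.04, "Y": 10.3}
    },
    "Thurlkill": {
      "n_term": 8.0, "c_term": 3.67,
      "side_chain": {"C": 8.55, "D": 3.67, "E": 4.25, "H": 6.54, "K": 10.4, "R": 12.0, "Y": 9.84}
    },
    "Toseland": {
      "n_term": 8.71, "c_term": 3.19,
      "side_chain": {"C": 6.87, "D": 3.6, "E": 4.29, "H": 6.33, "K": 10.45, "R": 12.0, "Y": 9.61}
    },
    "Nozaki": {
      "n_term": 7.5, "c_term": 3.8,
      "side_chain": {"C": 9.5, "D": 4.0, "E": 4.4, "H": 6.3, "K": 10.4, "R": 12.0, "Y": 9.6}
    },
    "Wikipedia": {
      "n_term": 8.2, "c_term": 3.65,
      "side_chain": {"C": 8.18, "D": 3.9, "E": 4.07, "H": 6.04, "K": 10.54, "R": 12.48, "Y": 10.46}
    },
    "Patrickios": {
      "n_term": 11.2, "c_term": 4.2,
      "side_chain": {"D": 4.2, "E": 4.2, "K": 11.2, "R": 11.2}
    },
    "IPC_protein": {
      "n_term": 9.094, "c_term": 2.869,
      "side_chain": {"C": 7.555, "D": 3.872, "E": 4.412, "H": 5.637, "K": 9.052, "R": 11.84, "Y": 10.85}
    },
    "IPC_peptide": {
      "n_term": 9.564, "c_term": 2.383,
      "side_chain": {"C": 8.297, "D": 3.887, "E": 4.317, "H": 6.018, "K": 10.517, "R": 12.503, "Y": 10.071}
    },
    "IPC2_protein": {
      "n_term": 7.947, "c_term": 2.977,
      "side_chain": {"C": 7.961, "D": 3.969, "E": 4.504, "H": 6.439, "K": 9.247, "R": 11.24, "Y": 9.439}
    },
    "IPC2_peptide": {
      "n_term": 8.196, "c_term": 3.055,
      "side_chain": {"C": 8.297, "D": 3.887, "E": 4.317, "H": 6.018, "K": 10.517, "R": 12.503, "Y": 10.071}
    },
    "Bjellqvist": {
      "n_term": 7.5, "c_term": 3.55,
      "side_chain": {"C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0, "Y": 10.0},
      "n_term_by_residue": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7},
      "side_chain_positional": {
        "D": {"c_term": 4.55},
        "E": {"c_term": 4.75}
      }
    },
    "ProMoST": {
      "n_term": 7.26, "c_term": 3.57,
      "side_chain": {"C": 8.28, "D": 4.07, "E": 4.45, "H": 6.08, "K": 10.0, "R": 12.0, "Y": 9.84},
      "n_term_by_residue": {
        "G": 7.5, "A": 7.58, "S": 6.86, "P": 8.36, "V": 7.44, "T": 7.02,
        "C": 8.12, "I": 7.48, "L": 7.46, "N": 7.22, "D": 7.7, "Q": 6.73,
        "K": 6.67, "E": 7.19, "M": 6.98, "H": 7.18, "F": 6.96, "R": 6.76,
        "Y": 6.83, "W": 7.11
      },
      "c_term_by_residue": {
        "G": 3.7, "A": 3.75, "S": 3.61, "P": 3.4, "V": 3.69, "T": 3.57,
        "C": 3.1, "I": 3.72, "L": 3.73, "N": 3.64, "D": 3.5, "Q": 3.57,
        "K": 3.4, "E": 3.5, "M": 3.68, "H": 3.17, "F": 3.98, "R": 3.41,
        "Y": 3.6, "W": 3.78
      },
      "side_chain_positional": {
        "D": {"n_term": 3.57, "c_term": 4.57},
        "E": {"n_term": 4.15, "c_term": 4.75},
        "C": {"n_term": 8.0, "c_term": 9.0},
        "Y": {"n_term": 9.34, "c_term": 10.34},
        "H": {"n_term": 4.89, "c_term": 6.89},
        "K": {"n_term": 10.3, "c_term": 11.1},
        "R": {"n_term": 11.5, "c_term": 12.5}
      }
    }
  }
}
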