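{
  "schema_version": 1,
  "comment": "Bundled amino-acid property scales (one value per standard residue). A small canonical subset; the full AAindex1 flat file can be loaded with features.read_aaindex1.",
  "scales": {
    "hydropathy_kyte_doolittle": {
      "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
      "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
      "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3
    },
    "hydrophilicity_hopp_woods": {
      "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0, "H": -0.5,
      "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2,
      "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3
    },
    "hydrophobicity_eisenberg": {
      "A": 0.62, "C": 0.29, "D": -0.9, "E": -0.74, "F": 1.19, "G": 0.48,
      "H": -0.4, "I": 1.38, "K": -1.5, "L": 1.06, "M": 0.64, "N": -0.78,
      "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
      "W": 0.81, "Y": 0.26
    },
    "hydrophobicity_fauchere_pliska": {
      "A": 0.31, "C": 1.54, "D": -0.77, "E": -0.64, "F": 1.79, "G": 0.0,
      "H": 0.13, "I": 1.8, "K": -0.99, "L": 1.7, "M": 1.23, "N": -0.6,
      "P": 0.72, "Q": -0.22, "R": -1.01, "S": -0.04, "T": 0.26, "V": 1.22,
      "W": 2.25, "Y": 0.96
    },
    "bulkiness_zimmerman": {
      "A": 11.5, "C": 13.46, "D": 11.68, "E": 13.57, "F": 19.8, "G": 3.4,
      "H": 13.69, "I": 21.4, "K": 15.71, "L": 21.4, "M": 16.25, "N": 12.82,
      "P": 17.43, "Q": 14.45, "R": 14.28, "S": 9.47, "T": 15.77, "V": 21.57,
      "W": 21.67, "Y": 18.03
    },
    "polarity_zimmerman": {
      "A": 0.0, "C": 1.48, "D": 49.7, "E": 49.9, "F": 0.35, "G": 0.0,
      "H": 51.6, "I": 0.13, "K": 49.5, "L": 0.13, "M": 1.43, "N": 3.38,
      "P": 1.58, "Q": 3.53, "R": 52.0, "S": 1.67, "T": 1.66, "V": 0.13,
      "W": 2.1, "Y": 1.61
    },
    "polarity_grantham": {
      "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0, "H": 10.4,
      "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5,
      "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2
    },
    "residue_volume": {
      "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9, "G": 60.1,
      "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7, "M": 162.9, "N": 114.1,
      "P": 112.7, "Q": 143.8, "R": 173.4, "S": 89.0, "T": 116.1, "V": 140.0,
      "W": 227.8, "Y": 193.6
    },
    "net_charge_ph7": {
      "A": 0.0, "C": 0.0, "D": -1.0, "E": -1.0, "F": 0.0, "G": 0.0, "H": 0.1,
      "I": 0.0, "K": 1.0, "L": 0.0, "M": 0.0, "N": 0.0, "P": 0.0, "Q": 0.0,
      "R": 1.0, "S": 0.0, "T": 0.0, "V": 0.0, "W": 0.0, "Y": 0.0
    },
    "isoelectric_point_free_aa": {
      "A": 6.0, "C": 5.05, "D": 2.77, "E": 3.22, "F": 5.48, "G": 5.97,
      "H": 7.59, "I": 6.02, "K": 9.74, "L": 5.98, "M": 5.74, "N": 5.41,
      "P": 6.3, "Q": 5.65, "R": 10.76, "S": 5.68, "T": 5.66, "V": 5.96,
      "W": 5.89, "Y": 5.66
    },
    "side_chain_pka_emboss": {
      "A": 0.0, "C": 8.5, "D": 3.9, "E": 4.1, "F": 0.0, "G": 0.0, "H": 6.5,
      "I": 0.0, "K": 10.8, "L": 0.0, "M": 0.0, "N": 0.0, "P": 0.0, "Q": 0.0,
      "R": 12.5, "S": 0.0, "T": 0.0, "V": 0.0, "W": 0.0, "Y": 10.1
    },
    "flexibility_bhaskaran_ponnuswamy": {
      "A": 0.357, "C": 0.346, "D": 0.511, "E": 0.497, "F": 0.314, "G": 0.544,
      "H": 0.323, "I": 0.462, "K": 0.466, "L": 0.365, "M": 0.295, "N": 0.463,
      "P": 0.509, "Q": 0.493, "R": 0.529, "S": 0.507, "T": 0.444, "V": 0.386,
      "W": 0.305, "Y": 0.42
    },
    "refractivity": {
      "A": 4.34, "C": 35.77, "D": 12.0, "E": 17.26, "F": 29.4, "G": 0.0,
      "H": 21.81, "I": 19.06, "K": 21.29, "L": 18.78, "M": 21.64, "N": 13.28,
      "P": 10.93, "Q": 17.56, "R": 26.66, "S": 6.35, "T": 11.01, "V": 13.92,
      "W": 42.53, "Y": 31.53
    },
    "transfer_energy_janin": {
      "A": 0.3, "C": 0.9, "D": -0.6, "E": -0.7, "F": 0.5, "G": 0.3, "H": -0.1,
      "I": 0.7, "K": -1.8, "L": 0.5, "M": 0.4, "N": -0.5, "P": -0.3, "Q": -0.7,
      "R": -1.4, "S": -0.1, "T": -0.2, "V": 0.6, "W": 0.3, "Y": -0.4
    },
    "helix_propensity_chou_fasman": {
      "A": 1.42, "C": 0.7, "D": 1.01, "E": 1.51, "F": 1.13, "G": 0.57,
      "H": 1.0, "I": 1.08, "K": 1.16, "L": 1.21, "M": 1.45, "N": 0.67,
      "P": 0.57, "Q": 1.11, "R": 0.98, "S": 0.77, "T": 0.83, "V": 1.06,
      "W": 1.08, "Y": 0.69
    },
    "sheet_propensity_chou_fasman": {
      "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38, "G": 0.75,
      "H": 0.87, "I": 1.6, "K": 0.74, "L": 1.3, "M": 1.05, "N": 0.89,
      "P": 0.55, "Q": 1.1, "R": 0.93, "S": 0.75, "T": 1.19, "V": 1.7,
      "W": 1.37, "Y": 1.47
    },
    "turn_propensity_chou_fasman": {
      "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.6, "G": 1.56,
      "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59, "M": 0.6, "N": 1.56,
      "P": 1.52, "Q": 0.98, "R": 0.95, "S": 1.43, "T": 0.96, "V": 0.5,
      "W": 0.96, "Y": 1.14
    },
    "residue_mass_average": {
      "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
      "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
      "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
      "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.176
    },
    "aromaticity_indicator": {
      "A": 0.0, "C": 0.0, "D": 0.0, "E": 0.0, "F": 1.0, "G": 0.0, "H": 0.0,
      "I": 0.0, "K": 0.0, "L": 0.0, "M": 0.0, "N": 0.0, "P": 0.0, "Q": 0.0,
      "R": 0.0, "S": 0.0, "T": 0.0, "V": 0.0, "W": 1.0, "Y": 1.0
    },
    "aliphatic_indicator": {
      "A": 1.0, "C": 0.0, "D": 0.0, "E": 0.0, "F": 0.0, "G": 0.0, "H": 0.0,
      "I": 1.0, "K": 0.0, "L": 1.0, "M": 0.0, "N": 0.0, "P": 0.0, "Q": 0.0,
      "R": 0.0, "S": 0.0, "T": 0.0, "V": 1.0, "W": 0.0, "Y": 0.0
    }
  }
}
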