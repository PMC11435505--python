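{
  "target": "PEC3_CLASS",
  "latent": ["CYTOX", "CYSTEINE", "HCLAT", "BIOAV", "INSILICO"],
  "nodes": {
    "PEC3_CLASS": 4,
    "CYTOX": null,
    "CYSTEINE": null,
    "HCLAT": null,
    "BIOAV": null,
    "INSILICO": null,
    "KS_EC15": 4,
    "KS_EC3": 4,
    "KS_IC50": 4,
    "DPRA_CYS": 4,
    "DPRA_LYS": 4,
    "KMAX": 4,
    "KDPRA_CLASS": 2,
    "HCLAT_EC150": 4,
    "HCLAT_EC200": 4,
    "HCLAT_CV75": 4,
    "LOG_KOW": 4,
    "LOG_D": 4,
    "WS": 4,
    "PROTEIN_BINDING": 4,
    "F_ION": 4,
    "SKIN_DOCTOR": 3,
    "DEREK": 4
  },
  "edges": [
    ["PEC3_CLASS", "CYTOX"],
    ["PEC3_CLASS", "CYSTEINE"],
    ["PEC3_CLASS", "HCLAT"],
    ["PEC3_CLASS", "BIOAV"],
    ["PEC3_CLASS", "INSILICO"],
    ["CYTOX", "KS_EC15"],
    ["CYTOX", "KS_EC3"],
    ["CYTOX", "KS_IC50"],
    ["CYSTEINE", "DPRA_CYS"],
    ["CYSTEINE", "DPRA_LYS"],
    ["CYSTEINE", "KMAX"],
    ["CYSTEINE", "KDPRA_CLASS"],
    ["HCLAT", "HCLAT_EC150"],
    ["HCLAT", "HCLAT_EC200"],
    ["HCLAT", "HCLAT_CV75"],
    ["BIOAV", "LOG_KOW"],
    ["BIOAV", "LOG_D"],
    ["BIOAV", "WS"],
    ["BIOAV", "PROTEIN_BINDING"],
    ["BIOAV", "F_ION"],
    ["INSILICO", "SKIN_DOCTOR"],
    ["INSILICO", "DEREK"]
  ]
}
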