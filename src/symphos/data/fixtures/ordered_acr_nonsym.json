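{
  "name": "ordered_acr_nonsym",
  "network": {
    "topology": "ordered_dsp",
    "kinase_mode": "common",
    "phosphatase_mode": "common",
    "dephosphorylation": "distributive"
  },
  "parameters": {
    "triplets": {
      "d:Ap>A": {
        "k_on": 0.9,
        "k_off": 1.2,
        "k_cat": 1.7
      },
      "d:App>Ap": {
        "k_on": 1.4,
        "k_off": 0.7,
        "k_cat": 0.9
      },
      "p:A>Ap": {
        "k_on": 1.1,
        "k_off": 0.8,
        "k_cat": 1.0
      },
      "p:Ap>App": {
        "k_on": 1.2,
        "k_off": 1.0,
        "k_cat": 2.4234111711025594
      }
    },
    "totals": {
      "substrate_total": 2.0,
      "enzyme_totals": {
        "K": 1.0,
        "P": 1.3
      }
    }
  },
  "a_range": [
    2.0,
    40.0
  ],
  "case": null,
  "notes": "non-symmetric; k_cat of the second phosphorylation solves the Ap-ACR compatibility condition: two stable branches with Ap pinned at 2.66299 and one unstable branch crossing in a transcritical point at A=9.5497"
}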