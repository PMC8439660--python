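{
  "name": "ordered_case1",
  "network": {
    "topology": "ordered_dsp",
    "kinase_mode": "common",
    "phosphatase_mode": "common",
    "dephosphorylation": "distributive"
  },
  "parameters": {
    "triplets": {
      "d:Ap>A": {
        "k_on": 1,
        "k_off": 1,
        "k_cat": 2
      },
      "d:App>Ap": {
        "k_on": 1,
        "k_off": 1,
        "k_cat": 1
      },
      "p:A>Ap": {
        "k_on": 1,
        "k_off": 1,
        "k_cat": 1
      },
      "p:Ap>App": {
        "k_on": 1,
        "k_off": 1,
        "k_cat": 2
      }
    },
    "totals": {
      "substrate_total": 0.5,
      "enzyme_totals": {
        "K": 1.0,
        "P": 1.0
      }
    }
  },
  "a_range": [
    0.5,
    30.0
  ],
  "case": "case1",
  "notes": "k2 = 2 k1; supercritical pitchfork at A_Total = 12.5; Ap pinned at 3 on the asymmetric branches"
}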