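{
  "name": "case3_ckcp_hopf",
  "network": {
    "topology": "random_dsp",
    "kinase_mode": "common",
    "phosphatase_mode": "common",
    "dephosphorylation": "distributive"
  },
  "parameters": {
    "triplets": {
      "d:A01>A00": {
        "k_on": 0.31595082676962766,
        "k_off": 3.7976272757268137,
        "k_cat": 3.577460640626348
      },
      "d:A10>A00": {
        "k_on": 1.8541214000577146,
        "k_off": 1.1104577263138284,
        "k_cat": 36.830004338281185
      },
      "d:A11>A01": {
        "k_on": 1.939502108117541,
        "k_off": 1.5856298036280339,
        "k_cat": 15.526234819332787
      },
      "d:A11>A10": {
        "k_on": 8.454536783304956,
        "k_off": 0.9256630095850317,
        "k_cat": 0.9419701528408689
      },
      "p:A00>A01": {
        "k_on": 8.454536783304956,
        "k_off": 0.9256630095850317,
        "k_cat": 0.9419701528408689
      },
      "p:A00>A10": {
        "k_on": 1.939502108117541,
        "k_off": 1.5856298036280339,
        "k_cat": 15.526234819332787
      },
      "p:A01>A11": {
        "k_on": 1.8541214000577146,
        "k_off": 1.1104577263138284,
        "k_cat": 36.830004338281185
      },
      "p:A10>A11": {
        "k_on": 0.31595082676962766,
        "k_off": 3.7976272757268137,
        "k_cat": 3.577460640626348
      }
    },
    "totals": {
      "substrate_total": 0.5088030548168032,
      "enzyme_totals": {
        "K": 0.6712689137583808,
        "P": 0.6712689137583808
      }
    }
  },
  "a_range": [
    0.013425378275167616,
    25.0
  ],
  "case": "case3",
  "notes": "seed 11; Hopf at A=5.71 followed by pitchfork at A=12.39; sustained oscillations with period growing with A_Total"
}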