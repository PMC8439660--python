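{
  "name": "case3_sksp_super",
  "network": {
    "topology": "random_dsp",
    "kinase_mode": "separate",
    "phosphatase_mode": "separate",
    "dephosphorylation": "distributive"
  },
  "parameters": {
    "triplets": {
      "d:A01>A00": {
        "k_on": 0.31595082676962766,
        "k_off": 3.7976272757268137,
        "k_cat": 4.243112844004989
      },
      "d:A10>A00": {
        "k_on": 1.8541214000577146,
        "k_off": 1.1104577263138284,
        "k_cat": 73.06123235809257
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
        "k_cat": 73.06123235809257
      },
      "p:A10>A11": {
        "k_on": 0.31595082676962766,
        "k_off": 3.7976272757268137,
        "k_cat": 4.243112844004989
      }
    },
    "totals": {
      "substrate_total": 0.5088030548168032,
      "enzyme_totals": {
        "K1": 2.4762699516273647,
        "K2": 1.2665862922103,
        "P1": 2.4762699516273647,
        "P2": 1.2665862922103
      }
    }
  },
  "a_range": [
    0.049525399032547296,
    85.0
  ],
  "case": "case3",
  "notes": "seed 11; supercritical pitchfork near A=37.97; no exact invariant, sum of partial forms approximately constant"
}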