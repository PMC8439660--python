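{
  "name": "case3_sksp_hopf",
  "network": {
    "topology": "random_dsp",
    "kinase_mode": "separate",
    "phosphatase_mode": "separate",
    "dephosphorylation": "distributive"
  },
  "parameters": {
    "triplets": {
      "d:A01>A00": {
        "k_on": 38.361521895812054,
        "k_off": 2.336260768594452,
        "k_cat": 4.856306272231686
      },
      "d:A10>A00": {
        "k_on": 55.86046881968358,
        "k_off": 2.5706671525967018,
        "k_cat": 3.286934101376694
      },
      "d:A11>A01": {
        "k_on": 8.021284667178213,
        "k_off": 2.615486697984917,
        "k_cat": 4.742904740967204
      },
      "d:A11>A10": {
        "k_on": 6.745318660865611,
        "k_off": 16.73282443996487,
        "k_cat": 0.4937238948945996
      },
      "p:A00>A01": {
        "k_on": 6.745318660865611,
        "k_off": 16.73282443996487,
        "k_cat": 0.4937238948945996
      },
      "p:A00>A10": {
        "k_on": 8.021284667178213,
        "k_off": 2.615486697984917,
        "k_cat": 4.742904740967204
      },
      "p:A01>A11": {
        "k_on": 55.86046881968358,
        "k_off": 2.5706671525967018,
        "k_cat": 3.286934101376694
      },
      "p:A10>A11": {
        "k_on": 38.361521895812054,
        "k_off": 2.336260768594452,
        "k_cat": 4.856306272231686
      }
    },
    "totals": {
      "substrate_total": 2.1706084612528764,
      "enzyme_totals": {
        "K1": 0.7982586177681943,
        "K2": 0.2051333450437738,
        "P1": 0.7982586177681943,
        "P2": 0.2051333450437738
      }
    }
  },
  "a_range": [
    0.015965172355363887,
    60.0
  ],
  "case": "case3",
  "notes": "seed 14; Hopf at A=36.56 with sustained oscillations above it"
}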