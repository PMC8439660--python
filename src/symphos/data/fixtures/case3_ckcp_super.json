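{
  "name": "case3_ckcp_super",
  "network": {
    "topology": "random_dsp",
    "kinase_mode": "common",
    "phosphatase_mode": "common",
    "dephosphorylation": "distributive"
  },
  "parameters": {
    "triplets": {
      "d:A01>A00": {
        "k_on": 38.361521895812054,
        "k_off": 2.336260768594452,
        "k_cat": 1.8930916179669388
      },
      "d:A10>A00": {
        "k_on": 55.86046881968358,
        "k_off": 2.5706671525967018,
        "k_cat": 8.77242643763137
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
        "k_cat": 8.77242643763137
      },
      "p:A10>A11": {
        "k_on": 38.361521895812054,
        "k_off": 2.336260768594452,
        "k_cat": 1.8930916179669388
      }
    },
    "totals": {
      "substrate_total": 2.1706084612528764,
      "enzyme_totals": {
        "K": 0.1529736570706403,
        "P": 0.1529736570706403
      }
    }
  },
  "a_range": [
    0.0030594731414128064,
    5.5
  ],
  "case": "case3",
  "notes": "seed 14, k3<k2 and k1<k4; supercritical pitchfork near A=2.25; sum of partial forms pinned"
}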