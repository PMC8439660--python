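{
  "name": "case3_ckcp_subcritical",
  "network": {
    "topology": "random_dsp",
    "kinase_mode": "common",
    "phosphatase_mode": "common",
    "dephosphorylation": "distributive"
  },
  "parameters": {
    "triplets": {
      "d:A01>A00": {
        "k_on": 0.18665484545863967,
        "k_off": 2.883414610253192,
        "k_cat": 1.030976598704347
      },
      "d:A10>A00": {
        "k_on": 1.3548554254723983,
        "k_off": 3.691124836585805,
        "k_cat": 0.791748011363968
      },
      "d:A11>A01": {
        "k_on": 13.314660433726232,
        "k_off": 11.8319420229238,
        "k_cat": 3.362948797558504
      },
      "d:A11>A10": {
        "k_on": 21.185324413633985,
        "k_off": 0.887777271129929,
        "k_cat": 0.15160126403307558
      },
      "p:A00>A01": {
        "k_on": 21.185324413633985,
        "k_off": 0.887777271129929,
        "k_cat": 0.15160126403307558
      },
      "p:A00>A10": {
        "k_on": 13.314660433726232,
        "k_off": 11.8319420229238,
        "k_cat": 3.362948797558504
      },
      "p:A01>A11": {
        "k_on": 1.3548554254723983,
        "k_off": 3.691124836585805,
        "k_cat": 0.791748011363968
      },
      "p:A10>A11": {
        "k_on": 0.18665484545863967,
        "k_off": 2.883414610253192,
        "k_cat": 1.030976598704347
      }
    },
    "totals": {
      "substrate_total": 0.30641765176670843,
      "enzyme_totals": {
        "K": 2.5062387941015265,
        "P": 2.5062387941015265
      }
    }
  },
  "a_range": [
    0.05012477588203053,
    21.0
  ],
  "case": "case3",
  "notes": "k3/k2 = 4.247 > 1, k1/k4 = 0.1470 < 1: subcritical pitchfork at A=9.323 with folds at A=9.307 on both asymmetric branches and a tristability window in between; sum of partial forms pinned at 5.1699"
}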